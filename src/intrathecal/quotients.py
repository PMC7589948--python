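"""CSF/serum quotients and hyperbolic (Reiber-type) reference functions.

Everything in this module works on concentrations expressed in mg/L.
Laboratories commonly report serum albumin and serum IgG in g/L; the
loading layer (:mod:`intrathecal.cohort`) converts to mg/L at ingestion so
that all quotients are dimensionless.

The quantities computed here are the standard CSF immunology panel:

* ``Qalb``, ``QIgG``, ``Qkappa`` — CSF/serum concentration quotients for
  albumin, IgG and kappa free light chains (KFLC).
* IgG index = QIgG / Qalb; kappa index = Qkappa / Qalb.
* ``Qlim(IgG)`` — the hyperbolic upper reference limit of QIgG as a
  function of Qalb; quotients above it indicate intrathecal IgG synthesis.
* Intrathecal IgG synthesis (local concentration, mg/L) =
  ``(QIgG − Qlim(IgG)) × serum IgG``; negative values are meaningful and
  are reported unmodified.
* KFLC intrathecal fraction, ``KFLC IF = (1 − Qlim(kappa)/Qkappa) × 100``,
  the percentage of CSF KFLC attributable to intrathecal synthesis
  relative to a hyperbolic reference line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "PairedSpecimen",
    "QuotientProfile",
    "HyperbolicCurveParams",
    "IGG_LIM",
    "KFLC_CURVES",
    "DEFAULT_DETECTION_LIMIT",
    "impute_censored_kflc",
    "compute_quotients",
    "qlim_igg",
    "reiber_igg_loc",
    "hyperbolic_curve",
    "kflc_if",
    "derive_profile",
]

#: Lower detection limit of the CSF KFLC assay, mg/L.
DEFAULT_DETECTION_LIMIT = 0.3


@dataclass(frozen=True)
class HyperbolicCurveParams:
    """Parameters of a hyperbolic quotient-diagram reference curve.

    The curve is ``Q(Qalb) = a * sqrt(Qalb**2 + b) - c`` with ``a > 0``,
    which is strictly increasing in Qalb and approaches the asymptote
    ``a * Qalb`` for large Qalb.

    Parameters
    ----------
    a : slope factor (dimensionless).
    b : additive constant under the square root (units of Qalb**2).
    c : offset subtracted from the square root term.
    label : which reference line this is ("lim", "mean" or "low").
    """

    a: float
    b: float
    c: float
    label: str = "lim"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"curve slope a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"curve constant b must be >= 0, got {self.b}")

    def __call__(self, q_alb: float) -> float:
        return hyperbolic_curve(q_alb, self)


#: Upper hyperbolic reference limit for QIgG.
IGG_LIM = HyperbolicCurveParams(a=0.93, b=6e-6, c=1.7e-3, label="lim")

# KFLC quotient-diagram curves.  The upper discrimination line Qkappa(lim)
# uses the published KFLC hyperbolic function a=3.27, b=33e-6, c=8.2e-3
# (quotient-diagram convention; quotients are absolute, not x10^-3).  The
# mean/low lines below are visual-band aids for diagram export only: they
# scale the lim curve and enter no statistic.  All three are configurable.
KFLC_CURVES = {
    "lim": HyperbolicCurveParams(a=3.27, b=33e-6, c=8.2e-3, label="lim"),
    "mean": HyperbolicCurveParams(a=3.27 * 0.55, b=33e-6, c=8.2e-3 * 0.55, label="mean"),
    "low": HyperbolicCurveParams(a=3.27 * 0.30, b=33e-6, c=8.2e-3 * 0.30, label="low"),
}


@dataclass(frozen=True)
class PairedSpecimen:
    """One patient's paired serum/CSF laboratory values, in mg/L.

    ``csf_kflc_censored`` is True when the CSF KFLC concentration was below
    the assay detection limit and has been imputed (detection limit / 2).
    """

    serum_albumin: float
    csf_albumin: float
    serum_igg: float
    csf_igg: float
    serum_kflc: float
    csf_kflc: float
    csf_kflc_censored: bool = False

    def __post_init__(self) -> None:
        for name in (
            "serum_albumin",
            "csf_albumin",
            "serum_igg",
            "csf_igg",
            "serum_kflc",
            "csf_kflc",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be > 0 (mg/L), got {value}")


@dataclass(frozen=True)
class QuotientProfile:
    """All derived CSF/serum quantities for one specimen.

    ``reiber_igg_loc`` (mg/L) and ``kflc_if`` (%) may be negative; negative
    values mean the measured quotient lies below the respective reference
    line.  They are None when not yet derived (see :func:`derive_profile`).
    """

    q_alb: float
    q_igg: float
    q_kappa: float
    kappa_index: float
    igg_index: float
    reiber_igg_loc: Optional[float] = None
    kflc_if: Optional[float] = None


def impute_censored_kflc(
    raw_value: Optional[float],
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> Tuple[float, bool]:
    """Impute a CSF KFLC value that is below the assay detection limit.

    Unmeasurable values (None or NaN) and values strictly below the
    detection limit are set to ``detection_limit / 2`` and flagged as
    censored; values at or above the limit pass through unchanged.

    Returns
    -------
    (value, censored) : the concentration in mg/L and the censoring flag.
    """
    if not detection_limit > 0:
        raise ValueError(f"detection_limit must be > 0, got {detection_limit}")
    if raw_value is None or (isinstance(raw_value, float) and math.isnan(raw_value)):
        return detection_limit / 2.0, True
    if raw_value < 0:
        raise ValueError(f"CSF KFLC concentration cannot be negative: {raw_value}")
    if raw_value < detection_limit:
        return detection_limit / 2.0, True
    return float(raw_value), False


def compute_quotients(spec: PairedSpecimen) -> QuotientProfile:
    """Compute Qalb, QIgG, Qkappa and the kappa and IgG indices.

    The kappa index is the CSF/serum KFLC quotient divided by the
    CSF/serum albumin quotient; the IgG index is defined analogously.
    The hyperbolic-reference quantities are left unset; use
    :func:`derive_profile` for the full panel.
    """
    q_alb = spec.csf_albumin / spec.serum_albumin
    q_igg = spec.csf_igg / spec.serum_igg
    q_kappa = spec.csf_kflc / spec.serum_kflc
    return QuotientProfile(
        q_alb=q_alb,
        q_igg=q_igg,
        q_kappa=q_kappa,
        kappa_index=q_kappa / q_alb,
        igg_index=q_igg / q_alb,
    )


def hyperbolic_curve(q_alb: float, params: HyperbolicCurveParams) -> float:
    """Evaluate ``a * sqrt(q_alb**2 + b) - c`` at the given albumin quotient."""
    if q_alb < 0:
        raise ValueError(f"q_alb must be >= 0, got {q_alb}")
    return params.a * math.sqrt(q_alb * q_alb + params.b) - params.c


def qlim_igg(q_alb: float) -> float:
    """Upper hyperbolic reference limit Qlim(IgG) at the given Qalb.

    ``Qlim(IgG) = 0.93 * sqrt(Qalb**2 + 6e-6) - 1.7e-3``.
    """
    return hyperbolic_curve(q_alb, IGG_LIM)


def reiber_igg_loc(q_igg: float, q_alb: float, serum_igg: float) -> float:
    """Intrathecally produced IgG concentration (mg/L).

    ``(QIgG − Qlim(IgG)) × serum IgG``.  Negative when QIgG lies below the
    reference limit; the sign is preserved.
    """
    return (q_igg - qlim_igg(q_alb)) * serum_igg


def kflc_if(
    q_kappa: float,
    q_alb: float,
    kflc_lim_params: HyperbolicCurveParams = KFLC_CURVES["lim"],
    *,
    clamp_negative: bool = False,
) -> float:
    """KFLC intrathecal fraction, ``(1 − Qlim(kappa)/Qkappa) × 100`` (%).

    Zero exactly on the reference line, strictly increasing in Qkappa,
    bounded above by 100.  Negative values (Qkappa below the line) are
    returned raw unless ``clamp_negative`` is set; positivity throughout
    the package means value > 0.
    """
    if not q_kappa > 0:
        raise ValueError(f"q_kappa must be > 0, got {q_kappa}")
    q_lim = hyperbolic_curve(q_alb, kflc_lim_params)
    value = (1.0 - q_lim / q_kappa) * 100.0
    if clamp_negative and value < 0:
        return 0.0
    return value


def derive_profile(
    spec: PairedSpecimen,
    kflc_lim_params: HyperbolicCurveParams = KFLC_CURVES["lim"],
    *,
    clamp_negative_if: bool = False,
) -> QuotientProfile:
    """Full derived panel: quotients, indices, Reiber IgG synthesis, KFLC IF."""
    base = compute_quotients(spec)
    return QuotientProfile(
        q_alb=base.q_alb,
        q_igg=base.q_igg,
        q_kappa=base.q_kappa,
        kappa_index=base.kappa_index,
        igg_index=base.igg_index,
        reiber_igg_loc=reiber_igg_loc(base.q_igg, base.q_alb, spec.serum_igg),
        kflc_if=kflc_if(
            base.q_kappa, base.q_alb, kflc_lim_params, clamp_negative=clamp_negative_if
        ),
    )
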