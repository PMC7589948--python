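"""Isoelectric-focusing (IEF) pattern taxonomy and derived binary markers.

The IEF pattern is a qualitative laboratory call on paired CSF/serum IgG
immunoblots.  Seven mutually exclusive categories are recognised; two
binary markers are derived from them:

* OCB positivity — at least two CSF-restricted oligoclonal IgG bands
  (the ``csf_restricted_ocb`` and ``mirror_plus_ocb`` patterns).
* OCB-or-single-band positivity — OCB positivity extended with the
  single-CSF-IgG-band patterns, which may represent very early
  intrathecal synthesis.

Monoclonal gammopathy is a systemic paraprotein pattern and counts as
negative for both markers.  Patterns are inputs, never inferred from gel
data.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["IEFPattern", "ocb_positive", "ocb_or_single_band_positive"]


class IEFPattern(str, Enum):
    """The seven IEF pattern categories."""

    POLYCLONAL = "polyclonal"
    MIRROR = "mirror"
    SINGLE_CSF_BAND = "single_csf_band"
    MIRROR_PLUS_SINGLE_BAND = "mirror_plus_single_band"
    CSF_RESTRICTED_OCB = "csf_restricted_ocb"
    MIRROR_PLUS_OCB = "mirror_plus_ocb"
    MONOCLONAL_GAMMOPATHY = "monoclonal_gammopathy"

    @classmethod
    def parse(cls, token: str, *, strict: bool = True) -> "IEFPattern":
        """Parse a CSV token into a pattern category.

        In lenient mode surrounding whitespace is stripped and case is
        ignored; strict mode requires the exact lowercase token.
        """
        candidate = token if strict else token.strip().lower()
        try:
            return cls(candidate)
        except ValueError:
            valid = ", ".join(p.value for p in cls)
            raise ValueError(
                f"unknown IEF pattern token {token!r}; expected one of: {valid}"
            ) from None


_OCB_POSITIVE = frozenset({IEFPattern.CSF_RESTRICTED_OCB, IEFPattern.MIRROR_PLUS_OCB})
_SINGLE_BAND = frozenset(
    {IEFPattern.SINGLE_CSF_BAND, IEFPattern.MIRROR_PLUS_SINGLE_BAND}
)


def _as_pattern(p: "IEFPattern | str") -> IEFPattern:
    if isinstance(p, IEFPattern):
        return p
    return IEFPattern.parse(p)


def ocb_positive(p: "IEFPattern | str") -> bool:
    """True iff the pattern shows >= 2 CSF-restricted oligoclonal bands."""
    return _as_pattern(p) in _OCB_POSITIVE


def ocb_or_single_band_positive(p: "IEFPattern | str") -> bool:
    """True iff OCB-positive or a single CSF IgG band is present."""
    pattern = _as_pattern(p)
    return pattern in _OCB_POSITIVE or pattern in _SINGLE_BAND
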