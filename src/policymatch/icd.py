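"""Packaged ICD-9/ICD-10 code maps.

Two independent maps live here:

* a *diagnosis* map used by the claims-indicator engine to classify
  patient-level diagnosis records into {oud, overdose, cancer, palliative,
  other} by code prefix, and
* the *mortality* tables: the underlying-cause codes that define a drug
  overdose death (X40–X44 unintentional, X60–X64 suicide, X85 homicide,
  Y10–Y14 undetermined intent) and the contributing T40.x codes that
  differentiate the drug involved (heroin T40.1, natural/semisynthetic
  opioids T40.2, methadone T40.3, synthetic opioids excl. methadone T40.4,
  cocaine T40.5, other/unspecified T40.6).

The diagnosis map is a deliberately small, documented stand-in for a full
claims code list; it is swappable via :class:`~policymatch.claims.IndicatorConfig`.
"""

from __future__ import annotations

import logging
import re

logger = logging.getLogger(__name__)

# Prefix → category, longest prefix wins. Codes are matched with dots stripped
# and upper-cased, so "T40.2X1A" and "T402X1A" are equivalent.
DIAGNOSIS_CODE_MAP: dict[int, dict[str, str]] = {
    10: {
        "F11": "oud",        # opioid-related disorders
        "T40": "overdose",   # poisoning by narcotics
        "C": "cancer",       # C00–C96 malignant neoplasms
        "Z515": "palliative",  # encounter for palliative care
    },
    9: {
        "3040": "oud",       # opioid type dependence
        "3055": "oud",       # opioid abuse
        "9650": "overdose",  # poisoning by opiates
        "E8501": "overdose",
        "V667": "palliative",
        # 140–208: malignant neoplasms
        **{str(c): "cancer" for c in range(140, 209)},
    },
}

# Underlying-cause codes gating a drug overdose death.
OVERDOSE_UNDERLYING: frozenset[str] = frozenset(
    [f"X{n}" for n in range(40, 45)]
    + [f"X{n}" for n in range(60, 65)]
    + ["X85"]
    + [f"Y{n}" for n in range(10, 15)]
)

# Contributing T-code → cause category (overlapping categories allowed).
T_CODE_CATEGORIES: dict[str, str] = {
    "T401": "heroin_T401",
    "T402": "natural_T402",
    "T403": "methadone_T403",
    "T404": "synthetic_T404",
    "T405": "cocaine_T405",
    "T406": "other_T406",
}

CAUSE_CATEGORIES: tuple[str, ...] = ("all_drug",) + tuple(T_CODE_CATEGORIES.values())

_CODE_RE = re.compile(r"^[A-Z0-9]+$")


def normalize_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def categorize_diagnosis(code: str, icd_version: int,
                         code_map: dict[int, dict[str, str]] | None = None) -> str:
    """Category of a diagnosis code, or 'other' when no prefix matches.

    Raises ValueError for an ICD version absent from the map (caller decides
    whether to reject the record or propagate).
    """
    cmap = (code_map or DIAGNOSIS_CODE_MAP).get(int(icd_version))
    if cmap is None:
        raise ValueError(f"unknown ICD version: {icd_version!r}")
    c = normalize_code(code)
    for plen in range(len(c), 0, -1):
        cat = cmap.get(c[:plen])
        if cat is not None:
            return cat
    return "other"


def is_overdose_underlying(code: str) -> bool:
    c = normalize_code(code)
    if not _CODE_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return c[:3] in OVERDOSE_UNDERLYING


def t_code_category(code: str) -> str | None:
    """Cause category of a contributing T-code, or None (e.g. T40.0, T40.7+)."""
    c = normalize_code(code)
    if not _CODE_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return T_CODE_CATEGORIES.get(c[:4])
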