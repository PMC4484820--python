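"""Packaged atlas label lists.

The feature table has one column per gray-matter region volume (AAL
parcellation, 116 regions, mL) and one per white-matter tract mean
fractional anisotropy (JHU ICBM-DTI-81 labels, 46 tracts, unitless).
Label lists ship as plain-text files versioned with the code so that
CSV headers are stable across runs.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = [
    "aal_regions",
    "jhu_tracts",
    "modality_of",
    "CLINICAL_CONTINUOUS",
    "CLINICAL_BINARY",
    "CLINICAL_COLUMNS",
]

#: clinical/demographic covariates carried in every cohort table
CLINICAL_CONTINUOUS = ("age", "hrsd17_baseline", "hrsd17_week8", "dose_mg_day")
CLINICAL_BINARY = ("sex", "melancholic", "prior_treatment")
CLINICAL_COLUMNS = ("age", "sex", "hrsd17_baseline", "hrsd17_week8",
                    "melancholic", "prior_treatment", "arm", "dose_mg_day")

TREATMENT_ARMS = ("escitalopram", "sertraline", "venlafaxine")


def _read_labels(name: str) -> tuple[str, ...]:
    text = resources.files("roctree.data").joinpath(name).read_text()
    return tuple(line.strip() for line in text.splitlines() if line.strip())


@lru_cache(maxsize=None)
def aal_regions() -> tuple[str, ...]:
    """The 116 AAL gray-matter region names (volume features, mL)."""
    return _read_labels("aal116_labels.txt")


@lru_cache(maxsize=None)
def jhu_tracts() -> tuple[str, ...]:
    """The 46 JHU ICBM-DTI-81 white-matter tract names (FA features)."""
    return _read_labels("jhu_icbm_dti81_labels.txt")


def modality_of(feature: str) -> str:
    """Classify a feature name as ``volumes``, ``fa`` or ``clinical``.

    Raises ``KeyError`` for names outside the packaged schemas.
    """
    if feature in aal_regions():
        return "volumes"
    if feature in jhu_tracts():
        return "fa"
    if feature in CLINICAL_COLUMNS:
        return "clinical"
    raise KeyError(f"unknown feature name: {feature!r}")
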