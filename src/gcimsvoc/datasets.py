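"""Bundled reference inputs.

The package was designed around a published three-group coeliac cohort —
13 coeliac-disease patients in remission on a gluten-free diet (CD), 7 with
refractory coeliac disease type II (RCD) and 10 non-coeliac endoscopic
controls (HC).  The raw chromatograms of that study are not deposited, but
its printed baseline characteristics are, and they serve here as reference
inputs for the exact contingency statistics.
"""

from __future__ import annotations

__all__ = ["STUDY_GROUP_SIZES", "baseline_dichotomous_counts"]

STUDY_GROUP_SIZES = {"CD": 13, "RCD": 7, "HC": 10}


def baseline_dichotomous_counts() -> dict:
    """Dichotomous baseline counts per group: ``{variable: {group: (yes, n)}}``.

    ``yes`` is the number of samples with the characteristic (female sex,
    current smoking, or use of the named medication in the three months
    before sampling); ``n`` the group size.
    """
    return {
        "sex_female": {"CD": (10, 13), "RCD": (3, 7), "HC": (6, 10)},
        "smoking": {"CD": (1, 13), "RCD": (0, 7), "HC": (1, 10)},
        "ppi": {"CD": (5, 13), "RCD": (6, 7), "HC": (4, 10)},
        "antibiotics": {"CD": (4, 13), "RCD": (2, 7), "HC": (0, 10)},
        "immunosuppressants": {"CD": (2, 13), "RCD": (5, 7), "HC": (0, 10)},
    }
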