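"""Submitting physician/surgeon (SPS) site attribution and profiling.

Each SPS is attributed to the hospital site where the largest number of the
specimens they submitted were accessioned (ties broken by lexicographically
smallest site label).  Profiles — volume, clinical-history-present count and
rate — are computed per SPS, with a minimum-volume filter (default 200
cases) for the provider-level analyses.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Sequence

import numpy as np

from .types import ClassifiedCase, SpsProfile

__all__ = ["assign_sps_sites", "sps_profiles", "profile_summary"]


def assign_sps_sites(cases: Sequence[ClassifiedCase]) -> dict[str, str]:
    """Map each SPS code to its modal accession site.

    Ties go to the lexicographically smallest site label; the result is
    invariant to case ordering.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for c in cases:
        counts[c.sps_code][c.site] += 1
    return {
        sps: min(sites, key=lambda s: (-sites[s], s))
        for sps, sites in counts.items()
    }


def sps_profiles(cases: Sequence[ClassifiedCase],
                 min_cases: int = 200) -> list[SpsProfile]:
    """One profile per SPS submitting at least ``min_cases`` cases,
    sorted by SPS code."""
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    assigned = assign_sps_sites(cases)
    volume: Counter = Counter()
    chp: Counter = Counter()
    for c in cases:
        volume[c.sps_code] += 1
        if c.is_chp:
            chp[c.sps_code] += 1
    return [
        SpsProfile(sps_code=sps, assigned_site=assigned[sps],
                   n_cases=volume[sps], n_chp=chp[sps])
        for sps in sorted(volume)
        if volume[sps] >= min_cases
    ]


def profile_summary(profiles: Sequence[SpsProfile]) -> dict[str, dict[str, float]]:
    """Mean / median / sample SD / max / min of per-SPS volume and CHP rate.

    SD uses the n-1 denominator; the median of an even count is the
    midpoint average.
    """
    if not profiles:
        raise ValueError("profile_summary requires at least one profile")
    out: dict[str, dict[str, float]] = {}
    for name, values in (
        ("n_cases", np.array([p.n_cases for p in profiles], dtype=float)),
        ("chp_rate", np.array([p.chp_rate for p in profiles], dtype=float)),
    ):
        out[name] = {
            "mean": float(np.mean(values)),
            "median": float(np.median(values)),
            "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
            "max": float(np.max(values)),
            "min": float(np.min(values)),
        }
    return out
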