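"""Short time-series profile clustering over the three molting stages.

Each transcript's stage-mean expression (v0, v1, v2) is normalised to
(0, log2(v1/v0), log2(v2/v0)) and assigned to the model profile (out of the
(2c+1)^(T-1) - 1 canonical templates; 8 for T=3, c=1) maximising the Pearson
correlation with its normalised vector. Transcripts failing the range filter
(max/min fold below a threshold) or the correlation filter are dropped.
Per-profile significance compares observed profile sizes with the expected
sizes under all 6 permutations of the stage labels (exhaustive for T=3).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd

from lncmolt.expression_de import bh_adjust


@dataclass(frozen=True)
class ModelProfile:
    profile_id: int
    template: tuple[float, ...]


def enumerate_profiles(n_timepoints: int = 3, c: int = 1) -> list[ModelProfile]:
    """All cumulative model profiles with unit steps in {-c..+c}, flat excluded.

    Templates start at 0 and are numbered lexicographically ascending by
    their coordinates after the first; there are (2c+1)^(T-1) - 1 of them.
    """
    if n_timepoints < 2 or c < 1:
        raise ValueError("need n_timepoints >= 2 and c >= 1")
    steps = range(-c, c + 1)
    templates = []
    for deltas in product(steps, repeat=n_timepoints - 1):
        if all(d == 0 for d in deltas):
            continue
        templates.append(tuple(float(x) for x in np.concatenate([[0.0], np.cumsum(deltas)])))
    templates.sort(key=lambda t: t[1:])
    return [ModelProfile(i, t) for i, t in enumerate(templates)]


def normalize_timecourse(
    v0: float, v1: float, v2: float, pseudocount: float = 1.0
) -> tuple[float, float, float]:
    """(0, log2((v1+eps)/(v0+eps)), log2((v2+eps)/(v0+eps)))."""
    eps = pseudocount
    return (
        0.0,
        float(np.log2((v1 + eps) / (v0 + eps))),
        float(np.log2((v2 + eps) / (v0 + eps))),
    )


@dataclass
class ProfileAssignment:
    transcript_id: str
    normalized: tuple[float, ...]
    profile_id: int = -1
    correlation: float = float("nan")
    kept: bool = False
    drop_reason: str = "none"  # low_range | low_correlation | none


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def assign_profile(
    transcript_id: str,
    raw: tuple[float, float, float],
    profiles: list[ModelProfile],
    min_correlation: float = 0.7,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> ProfileAssignment:
    """Assign a transcript's (v0, v1, v2) stage means to a model profile.

    Drops with reason ``low_range`` when the max/min fold change of the
    (pseudocount-stabilised) raw values is below ``min_fold`` or the
    normalised series is flat, and ``low_correlation`` when the best template
    correlation falls below ``min_correlation``. Ties between templates break
    toward the lowest profile id.
    """
    norm = normalize_timecourse(*raw, pseudocount=pseudocount)
    out = ProfileAssignment(transcript_id, norm)
    vals = np.asarray(raw, dtype=float) + pseudocount
    if vals.max() / vals.min() < min_fold:
        out.drop_reason = "low_range"
        return out
    nv = np.asarray(norm)
    if np.allclose(nv, nv[0]):
        out.drop_reason = "low_range"
        return out
    best_id, best_r = -1, -np.inf
    for p in profiles:
        r = _pearson(nv, np.asarray(p.template))
        if np.isnan(r):
            continue
        if r > best_r + 1e-12:
            best_id, best_r = p.profile_id, r
    out.profile_id = best_id
    out.correlation = float(best_r)
    if best_r < min_correlation:
        out.drop_reason = "low_correlation"
        return out
    out.kept = True
    return out


def assign_all(
    stage_means: pd.DataFrame,
    profiles: list[ModelProfile] | None = None,
    min_correlation: float = 0.7,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[ProfileAssignment]:
    """Assign every row of a (transcript x [PE, DE, AE]) stage-mean table."""
    if profiles is None:
        profiles = enumerate_profiles()
    return [
        assign_profile(
            str(tid),
            (float(row.iloc[0]), float(row.iloc[1]), float(row.iloc[2])),
            profiles,
            min_correlation,
            min_fold,
            pseudocount,
        )
        for tid, row in stage_means.iterrows()
    ]


def profile_significance(
    stage_means: pd.DataFrame,
    profiles: list[ModelProfile] | None = None,
    min_correlation: float = 0.7,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Permutation-expected profile sizes and enrichment p-values.

    The expected size of each profile is the mean assigned count over all 6
    permutations of the three stage labels (exhaustive for T = 3). The
    p-value is the upper tail of a binomial with the expected proportion;
    p-values are BH-adjusted across profiles.
    """
    if profiles is None:
        profiles = enumerate_profiles()
    cols = list(stage_means.columns)
    observed = assign_all(stage_means, profiles, min_correlation, min_fold, pseudocount)
    obs_counts = _profile_counts(observed, profiles)
    n_obs = sum(obs_counts.values())

    exp_counts = {p.profile_id: 0.0 for p in profiles}
    exp_total = 0.0
    perms = list(permutations(range(len(cols))))
    for perm in perms:
        permuted = stage_means.iloc[:, list(perm)]
        assigned = assign_all(permuted, profiles, min_correlation, min_fold, pseudocount)
        counts = _profile_counts(assigned, profiles)
        for pid, cnt in counts.items():
            exp_counts[pid] += cnt / len(perms)
        exp_total += sum(counts.values()) / len(perms)

    from scipy import stats as _stats

    rows = []
    for p in profiles:
        expected = exp_counts[p.profile_id]
        prop = min(1.0, expected / exp_total) if exp_total > 0 else 0.0
        k = obs_counts[p.profile_id]
        pval = float(_stats.binom.sf(k - 1, n_obs, prop)) if n_obs > 0 and prop > 0 else 1.0
        rows.append(
            {
                "profile_id": p.profile_id,
                "template": p.template,
                "observed": k,
                "expected": expected,
                "p_value": min(1.0, pval),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df


def _profile_counts(
    assignments: list[ProfileAssignment], profiles: list[ModelProfile]
) -> dict[int, int]:
    counts = {p.profile_id: 0 for p in profiles}
    for a in assignments:
        if a.kept:
            counts[a.profile_id] += 1
    return counts


def assignments_table(assignments: list[ProfileAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [a.transcript_id for a in assignments],
            "norm_v0": [a.normalized[0] for a in assignments],
            "norm_v1": [a.normalized[1] for a in assignments],
            "norm_v2": [a.normalized[2] for a in assignments],
            "profile_id": [a.profile_id for a in assignments],
            "correlation": [a.correlation for a in assignments],
            "kept": [a.kept for a in assignments],
            "drop_reason": [a.drop_reason for a in assignments],
        }
    )
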