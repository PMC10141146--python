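"""Relative expression from qPCR Ct tables via the 2^-ddCt method, with
one-way ANOVA and Tukey HSD compact letter groupings.

Each record pairs a target-gene Ct with a reference-gene Ct (internal
control) for one biological replicate. dCt = Ct(target) - Ct(reference);
ddCt = mean dCt(group) - mean dCt(calibrator group); RQ = 2^-ddCt. Because
the biological replicates are unpaired, ddCt uses the calibrator's group
mean; per-replicate RQ values (against that same calibrator mean) provide
the spread used in the ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene_id", "group", "replicate", "ct_target", "ct_reference")


def relative_expression(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per gene x group relative quantity RQ = 2^-ddCt with replicate values.

    Returns one row per gene x group with columns rq (group-level 2^-ddCt),
    rq_replicates (list of per-replicate RQs), and n. Records missing either
    Ct are dropped with a warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table lacks columns: {missing}")
    bad = records["ct_target"].isna() | records["ct_reference"].isna()
    if bad.any():
        import warnings

        warnings.warn(f"dropped {int(bad.sum())} record(s) with missing Ct", stacklevel=2)
        records = records[~bad]
    records = records.copy()
    records["dct"] = records["ct_target"] - records["ct_reference"]
    rows = []
    for gene, gene_grp in records.groupby("gene_id", sort=True):
        cal = gene_grp[gene_grp["group"] == calibrator_group]
        if cal.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} absent for gene {gene!r}"
            )
        cal_mean = cal["dct"].mean()
        for group, grp in gene_grp.groupby("group", sort=True):
            ddct = grp["dct"].mean() - cal_mean
            rep_rq = 2.0 ** -(grp["dct"] - cal_mean)
            rows.append(
                {
                    "gene_id": gene,
                    "group": group,
                    "rq": float(2.0**-ddct),
                    "rq_replicates": list(rep_rq),
                    "n": len(grp),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, q, p, significant
    letters: dict[str, str]
    zero_variance: bool = False
    alpha: float = 0.05


def anova_tukey(groups: dict[str, list[float]], alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA followed by Tukey's HSD with compact letter display.

    Groups sharing no significant pairwise difference share a letter.
    When every group has zero within-group variance the F test is undefined;
    groups are then separated exactly by their means and the result is
    flagged ``zero_variance``.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    means = {g: float(v.mean()) for g, v in data.items()}
    k = len(names)
    n_total = sum(v.size for v in data.values())
    df_within = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = sse / df_within

    if mse == 0:
        sig = {
            (a, b): means[a] != means[b] for i, a in enumerate(names) for b in names[i + 1 :]
        }
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "diff": means[b] - means[a],
                    "q": np.inf if s else 0.0,
                    "p": 0.0 if s else 1.0,
                    "significant": s,
                }
                for (a, b), s in sig.items()
            ]
        )
        letters = _compact_letters(names, means, sig)
        f = 0.0 if len(set(means.values())) == 1 else np.inf
        return TukeyResult(f, 1.0 if f == 0 else 0.0, pairwise, letters, True, alpha)

    f_stat, p_val = stats.f_oneway(*[data[g] for g in names])
    rows = []
    sig = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = means[b] - means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / data[a].size + 1.0 / data[b].size))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
            s = p < alpha
            sig[(a, b)] = s
            rows.append(
                {"group_a": a, "group_b": b, "diff": diff, "q": q, "p": p, "significant": s}
            )
    pairwise = pd.DataFrame(rows)
    letters = _compact_letters(names, means, sig)
    return TukeyResult(float(f_stat), float(p_val), pairwise, letters, False, alpha)


def _compact_letters(
    names: list[str],
    means: dict[str, float],
    significant: dict[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display by the sweep-and-absorb method.

    Groups are ordered by mean descending; for each group the maximal run of
    groups not significantly different from it forms a candidate letter set;
    sets contained in another are absorbed; remaining sets get letters a, b,
    ... in order of their best (highest-mean) member. Deterministic given the
    group means.
    """

    def is_sig(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    ordered = sorted(names, key=lambda g: (-means[g], g))
    runs: list[set[str]] = []
    for i, g in enumerate(ordered):
        run = {g}
        for h in ordered[i + 1 :]:
            if is_sig(g, h):
                break
            run.add(h)
        for h in reversed(ordered[:i]):
            if is_sig(g, h):
                break
            run.add(h)
        runs.append(run)
    # drop duplicates and runs contained in another run (absorption)
    unique: list[set[str]] = []
    for run in runs:
        if run not in unique:
            unique.append(run)
    kept = [r for r in unique if not any(r < o for o in unique)]
    kept.sort(key=lambda r: min(ordered.index(g) for g in r))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for idx, run in enumerate(kept):
        for g in run:
            letters[g] += alphabet[idx]
    return {g: "".join(sorted(letters[g])) for g in names}


def read_qpcr_table(path: str) -> pd.DataFrame:
    """Read a tab-separated qPCR Ct table."""
    return pd.read_csv(path, sep="\t")
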