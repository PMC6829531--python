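"""Differential abundance statistics for grouped metabolome/proteome tables.

The pipeline mirrors the standard label-free quantification workflow:
filter features to those fully observed in at least one group, impute
the remaining missing values from a down-shifted normal distribution,
run per-feature two-sample t-tests with Benjamini-Hochberg FDR control,
compare redox ratios (e.g. GSH/GSSG) across groups by one-way ANOVA with
Tukey HSD, and score a-priori feature sets with a weighted running-sum
enrichment statistic against a random-set permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class OmicsError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Features x samples abundance matrix with a group design.

    ``values`` holds positive intensities (or log2 intensities when
    ``log2`` is set); missing values are NaN. ``groups`` maps each sample
    column to its group label. Optional ``feature_sets`` carry class tags
    (e.g. complex I modules) used by the enrichment stage.
    """

    values: pd.DataFrame
    groups: pd.Series
    log2: bool = False
    feature_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        self.groups = pd.Series(self.groups)
        missing = [c for c in self.values.columns if c not in self.groups.index]
        if missing:
            raise OmicsError(f"samples without group labels: {missing}")
        if not self.log2:
            with np.errstate(invalid="ignore"):
                if (self.values <= 0).any().any():
                    raise OmicsError("raw intensities must be positive")

    @property
    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.groups.loc[self.values.columns]))

    def samples_of(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == group]

    def to_log2(self) -> "AbundanceTable":
        if self.log2:
            return self
        return replace(self, values=np.log2(self.values), log2=True)

    @classmethod
    def from_csv(cls, path: str, groups: dict[str, list[str]] | pd.Series,
                 log2: bool = False, sep: str = ",") -> "AbundanceTable":
        values = pd.read_csv(path, sep=sep, index_col=0)
        if isinstance(groups, dict):
            groups = pd.Series({s: g for g, ss in groups.items() for s in ss})
        return cls(values=values, groups=groups, log2=log2)

    def to_csv(self, path: str, sep: str = ",") -> None:
        self.values.to_csv(path, sep=sep)


def parse_groups(spec: str) -> dict[str, list[str]]:
    """Parse ``"a:s1,s2 b:s3,s4"`` into a group -> samples mapping."""
    out: dict[str, list[str]] = {}
    for token in spec.split():
        name, _, samples = token.partition(":")
        out[name] = samples.split(",")
    return out


def filter_valid(t: AbundanceTable) -> AbundanceTable:
    """Keep features with no missing value in at least one group."""
    keep = pd.Series(False, index=t.values.index)
    for g in t.group_names:
        cols = t.samples_of(g)
        keep |= t.values[cols].notna().all(axis=1)
    return replace(t, values=t.values.loc[keep])


def impute_missing(
    t: AbundanceTable, shift: float = 1.8, width: float = 0.3, seed: int | None = 0
) -> AbundanceTable:
    """Impute missing values from a down-shifted normal distribution.

    Per sample column, missing entries are drawn from
    ``Normal(mean - shift*SD, (width*SD)**2)`` of that column's observed
    log2 values. This emulates values missing because they fall below
    the detection limit.
    """
    if not t.log2:
        raise OmicsError("imputation expects a log2-transformed table")
    rng = np.random.default_rng(seed)
    values = t.values.copy()
    for col in values.columns:
        obs = values[col].dropna()
        n_missing = values[col].isna().sum()
        if n_missing == 0:
            continue
        if len(obs) < 3:
            raise OmicsError(f"sample {col!r} has fewer than 3 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        values.loc[values[col].isna(), col] = draws
    return replace(t, values=values)


def differential(
    t: AbundanceTable,
    group_a: str,
    group_b: str,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-sample t-test with BH correction on log2 values.

    Returns a DataFrame indexed by feature with columns ``log2fc``
    (mean(a) - mean(b)), ``t``, ``p``, ``q``, ``significant_t`` and
    ``significant_bh``. Features with zero variance in both groups and
    equal means get p = 1 by convention.
    """
    t = t.to_log2()
    a = t.values[t.samples_of(group_a)].to_numpy(dtype=float)
    b = t.values[t.samples_of(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise OmicsError("each compared group needs at least 2 replicates")
    if np.isnan(a).any() or np.isnan(b).any():
        raise OmicsError("run filter_valid/impute_missing before differential testing")

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    degenerate = np.isnan(tstat)
    equal_means = np.isclose(log2fc, 0.0)
    tstat = np.where(degenerate, 0.0, tstat)
    pval = np.where(degenerate & equal_means, 1.0, pval)
    pval = np.where(degenerate & ~equal_means, 0.0, pval)

    _, qval, _, _ = multipletests(pval, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "p": pval,
            "q": qval,
            "significant_t": pval <= alpha,
            "significant_bh": qval <= alpha,
        },
        index=t.values.index,
    )
    return out


def _degenerate_anova(arrays):
    # all within-group variance zero: F is 0/0 if means agree, infinite otherwise
    means = [a.mean() for a in arrays]
    if np.allclose(means, means[0]):
        return 0.0, 1.0
    return float("inf"), 0.0


@dataclass
class RedoxRatioResult:
    per_sample: pd.Series  # log2(numerator/denominator) per sample
    group_means: pd.Series
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # Tukey-adjusted pairwise p values


def redox_ratio(
    t: AbundanceTable, numerator: str = "GSH", denominator: str = "GSSG"
) -> RedoxRatioResult:
    """Group comparison of a per-sample log2 concentration ratio.

    One-way ANOVA across groups plus Tukey HSD pairwise comparisons
    (studentized-range adjusted p values).
    """
    for feat in (numerator, denominator):
        if feat not in t.values.index:
            raise OmicsError(f"feature {feat!r} not present in the table")
    row_n = t.values.loc[numerator]
    row_d = t.values.loc[denominator]
    if row_n.isna().any() or row_d.isna().any():
        raise OmicsError("ratio features must be observed in all samples")
    if t.log2:
        ratio = row_n - row_d
    else:
        ratio = np.log2(row_n / row_d)
    ratio = ratio.astype(float)

    groups = t.group_names
    arrays = [ratio[t.samples_of(g)].to_numpy() for g in groups]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled.var(), 0.0):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        if np.isnan(f_stat):  # zero within-group variance
            f_stat, p_val = _degenerate_anova(arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i < j:
                rows.append({"group_a": gi, "group_b": gj,
                             "p_adj": float(tukey.pvalue[i, j])})
    return RedoxRatioResult(
        per_sample=ratio,
        group_means=pd.Series({g: arr.mean() for g, arr in zip(groups, arrays)}),
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(rows),
    )


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    p: float
    q: float
    size: int
    excluded: bool = False
    reason: str = ""


def _running_sum_es(order: np.ndarray, scores: np.ndarray, member: np.ndarray,
                    weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``order`` is the descending-score ordering; hit increments are
    proportional to |score|^weight (normalized to 1), miss decrements
    are 1/(N - N_hit).
    """
    hits = member[order]
    w = np.abs(scores[order]) ** weight
    w_hit = np.where(hits, w, 0.0)
    total_hit = w_hit.sum()
    n_miss = len(order) - hits.sum()
    if total_hit == 0:  # all member scores exactly 0: uniform hit steps
        w_hit = hits.astype(float)
        total_hit = w_hit.sum()
    if n_miss == 0:
        return 1.0
    running = np.cumsum(w_hit / total_hit - (~hits) / n_miss)
    es = float(running[np.argmax(np.abs(running))])
    return max(-1.0, min(1.0, es))


def enrichment(
    ranked: pd.Series,
    sets: dict[str, tuple[str, ...] | list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 5,
    seed: int | None = 0,
) -> list[EnrichmentResult]:
    """Running-sum set enrichment over a ranked feature list.

    ``ranked`` maps feature id -> ranking score (e.g. log2 fold change);
    it is sorted descending internally. The null is built from random
    same-size feature sets (gene-set permutation), appropriate for the
    small replicate numbers typical of this kind of study. Nominal p is
    the one-sided tail frequency among same-signed null scores with +1
    smoothing; q is BH across the scored sets.
    """
    rng = np.random.default_rng(seed)
    scores = ranked.to_numpy(dtype=float)
    features = ranked.index.to_numpy()
    order = np.argsort(-scores, kind="stable")
    feat_pos = {f: i for i, f in enumerate(features)}
    n = len(features)

    results: list[EnrichmentResult] = []
    scored: list[EnrichmentResult] = []
    for set_id, members in sets.items():
        idx = [feat_pos[m] for m in members if m in feat_pos]
        size = len(idx)
        if size < min_size:
            results.append(
                EnrichmentResult(set_id=set_id, es=float("nan"), p=float("nan"),
                                 q=float("nan"), size=size, excluded=True,
                                 reason=f"size {size} below minimum {min_size}")
            )
            continue
        member = np.zeros(n, dtype=bool)
        member[idx] = True
        es = _running_sum_es(order, scores, member, weight)

        null = np.empty(n_perm)
        for b in range(n_perm):
            rand_member = np.zeros(n, dtype=bool)
            rand_member[rng.choice(n, size=size, replace=False)] = True
            null[b] = _running_sum_es(order, scores, rand_member, weight)
        if es >= 0:
            same = null[null >= 0]
            p = (1 + (same >= es).sum()) / (1 + len(same))
        else:
            same = null[null < 0]
            p = (1 + (same <= es).sum()) / (1 + len(same))
        res = EnrichmentResult(set_id=set_id, es=es, p=float(p), q=float("nan"), size=size)
        results.append(res)
        scored.append(res)

    if scored:
        _, qvals, _, _ = multipletests([r.p for r in scored], method="fdr_bh")
        for r, q in zip(scored, qvals):
            r.q = float(q)
    return results


def module_map(
    delta: pd.DataFrame, module_lists: dict[str, tuple[str, ...] | list[str]]
) -> pd.DataFrame:
    """Per-module summary of differential results for structure mapping.

    Returns one row per module with the mean and median log2 fold change
    over members present in the data; members absent from the table are
    counted as not detected (``n_nd``) and excluded from the summaries.
    """
    rows = []
    for label, members in module_lists.items():
        present = [m for m in members if m in delta.index]
        nd = [m for m in members if m not in delta.index]
        fc = delta.loc[present, "log2fc"] if present else pd.Series(dtype=float)
        rows.append(
            {
                "module": label,
                "n_members": len(members),
                "n_detected": len(present),
                "n_nd": len(nd),
                "mean_log2fc": float(fc.mean()) if len(fc) else float("nan"),
                "median_log2fc": float(fc.median()) if len(fc) else float("nan"),
                "members_detected": ",".join(present),
                "members_nd": ",".join(nd),
            }
        )
    return pd.DataFrame(rows).set_index("module")
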