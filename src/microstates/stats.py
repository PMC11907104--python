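"""Group statistics for microstate parameters, syntax and topographies.

The battery: mixed ANOVAs (group between, microstate class within, with
Mauchly's sphericity test and Greenhouse-Geisser correction), Welch t-tests
with Cohen's d, Bonferroni-corrected comparisons of the 12 ordered
transition pairs, and a randomization TANOVA on GFP-normalized scalp maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "StatTestResult",
    "TanovaResult",
    "mixed_anova",
    "welch_t",
    "cohens_d",
    "compare_transitions",
    "tanova",
]

logger = logging.getLogger(__name__)


@dataclass
class StatTestResult:
    name: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    p_corrected: float | None = None
    effect_size: float | None = None
    effect_size_kind: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject_id",
    within: str = "class",
    between: str = "group",
    alpha_sphericity: float = 0.05,
) -> list[StatTestResult]:
    """Mixed ANOVA: one between-subjects and one within-subjects factor.

    Returns F, degrees of freedom, p and partial eta squared for the group,
    class and interaction effects.  Mauchly's test is evaluated for the
    within factor; when sphericity is rejected at ``alpha_sphericity``, a
    Greenhouse-Geisser epsilon correction is applied to the class AND the
    interaction degrees of freedom.
    """
    data = table[[subject, within, between, dv]].dropna(subset=[dv])
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    incomplete = counts[counts < n_levels]
    if len(incomplete):
        raise ValueError(f"missing within-factor cells for subjects: {list(incomplete.index)}")
    if data.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")

    if np.ptp(data[dv].to_numpy()) == 0:
        # constant response: no effect and no error variance anywhere
        n_subj = data[subject].nunique()
        n_grp = data[between].nunique()
        dfs = {
            "group": (n_grp - 1, n_subj - n_grp),
            "class": (n_levels - 1, (n_subj - n_grp) * (n_levels - 1)),
            "interaction": ((n_grp - 1) * (n_levels - 1), (n_subj - n_grp) * (n_levels - 1)),
        }
        return [
            StatTestResult(
                name=f"{dv}:{eff}", statistic=0.0, df=tuple(map(float, d)), p=1.0,
                effect_size=0.0, effect_size_kind="partial_eta_sq",
            )
            for eff, d in dfs.items()
        ]

    aov = pg.mixed_anova(
        data, dv=dv, within=within, subject=subject, between=between, correction=True
    ).set_index("Source")
    g, w, ix = aov.loc[between], aov.loc[within], aov.loc["Interaction"]

    eps = float(w["eps"]) if "eps" in w.index else float("nan")
    sphericity_ok = bool(w["sphericity"]) if "sphericity" in w.index else True
    correct = (not bool(sphericity_ok)) and np.isfinite(eps)

    def _row(name: str, r: pd.Series, corrected: bool) -> StatTestResult:
        df1, df2, F = float(r["DF1"]), float(r["DF2"]), float(r["F"])
        if not np.isfinite(F):
            # degenerate input (zero effect and zero error variance): report
            # no evidence against the null rather than NaN
            return StatTestResult(
                name=name, statistic=0.0, df=(df1, df2), p=1.0,
                effect_size=0.0, effect_size_kind="partial_eta_sq",
            )
        if corrected:
            df1, df2 = eps * df1, eps * df2
            p = float(sps.f.sf(F, df1, df2))
        else:
            p = float(r["p-unc"] if "p-unc" in r else r["p_unc"])
        return StatTestResult(
            name=name,
            statistic=F,
            df=(df1, df2),
            p=p,
            effect_size=float(r["np2"]),
            effect_size_kind="partial_eta_sq",
        )

    return [
        _row(f"{dv}:group", g, False),
        _row(f"{dv}:class", w, correct),
        _row(f"{dv}:interaction", ix, correct),
    ]


def welch_t(a: np.ndarray, b: np.ndarray, name: str = "welch_t") -> StatTestResult:
    """Welch's unequal-variance two-sample t-test, two-tailed.

    Degrees of freedom follow Welch-Satterthwaite and are generally
    fractional.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatTestResult(
        name=name,
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        effect_size=cohens_d(a, b),
        effect_size_kind="cohens_d",
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def compare_transitions(
    tables_a: list[np.ndarray],
    tables_b: list[np.ndarray],
    labels: tuple[str, ...] = ("A", "B", "C", "D"),
) -> list[StatTestResult]:
    """Welch t-tests on per-subject transition percentages, Bonferroni m=12.

    ``tables_a`` / ``tables_b`` are per-subject K x K percentage matrices
    (NaN rows where a subject had no outgoing transition from a class; such
    subjects are dropped from that pair's test with a logged count).
    """
    K = len(labels)
    A = np.array(tables_a, dtype=float)
    B = np.array(tables_b, dtype=float)
    m = K * (K - 1)
    out = []
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            a, b = A[:, i, j], B[:, i, j]
            n_drop = int(np.isnan(a).sum() + np.isnan(b).sum())
            if n_drop:
                logger.info(
                    "transition %s->%s: dropped %d subject(s) with undefined row",
                    labels[i], labels[j], n_drop,
                )
            res = welch_t(a, b, name=f"transition:{labels[i]}->{labels[j]}")
            res.p_corrected = min(1.0, m * res.p)
            out.append(res)
    return out


@dataclass
class TanovaResult:
    """Randomization test on group-mean topographies.

    ``observed_effect`` is the GFP of the difference between the two groups'
    mean maps after each subject map is normalized to unit GFP.
    """

    observed_effect: float
    n_permutations: int
    p: float
    seed: int


def _gfp_of(v: np.ndarray) -> np.ndarray:
    """Population SD across the channel axis (last axis)."""
    return np.asarray(v, dtype=float).std(axis=-1, ddof=0)


def tanova(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    subject_ids: list[str] | None = None,
) -> TanovaResult:
    """Topographic analysis of variance between two groups of subject maps.

    Each subject's map is strength-normalized (divided by its GFP) so that
    only the spatial distribution, not amplitude, is compared.  The effect
    statistic is the GFP of the group-mean difference map; its null
    distribution comes from reshuffling subjects between groups preserving
    group sizes.  p uses the add-one estimator (never exactly 0).
    """
    A = np.atleast_2d(np.asarray(maps_a, dtype=float))
    B = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the montage")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    X = np.vstack([A, B])
    X = X - X.mean(axis=1, keepdims=True)
    g = _gfp_of(X)
    if np.any(g == 0):
        bad = int(np.argmax(g == 0))
        sid = subject_ids[bad] if subject_ids else f"#{bad}"
        raise ValueError(f"zero-GFP map for subject {sid}")
    X = X / g[:, None]

    na = A.shape[0]
    observed = float(_gfp_of(X[:na].mean(axis=0) - X[na:].mean(axis=0)))
    null = _tanova_null(X, na, n_permutations, seed)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return TanovaResult(
        observed_effect=observed, n_permutations=n_permutations, p=float(p), seed=seed
    )


def _tanova_null(X: np.ndarray, na: int, n_permutations: int, seed: int) -> np.ndarray:
    """Permutation null effects (vectorized).

    Subjects are put in a canonical (lexicographic) order before drawing
    permutations, and the smaller group size defines the random subset, so
    the null — and hence p — is exactly invariant to relabeling the groups
    and to the input ordering of subjects.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    k = min(na, n - na)
    Xc = X[np.lexsort(X.T[::-1])]
    idx = np.empty((n_permutations, n), dtype=int)
    for r in range(n_permutations):
        idx[r] = rng.permutation(n)
    mean_a = Xc[idx[:, :k]].mean(axis=1)
    mean_b = Xc[idx[:, k:]].mean(axis=1)
    return _gfp_of(mean_a - mean_b)
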