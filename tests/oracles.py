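"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's vectorized code paths: GEV by direct
per-map summation with scipy's Pearson correlation, and the globally optimal
K=3 clustering by exhaustive enumeration of all set partitions (the optimal
cluster template is the top eigenvector of the weighted outer-product sum,
so each block's best GEV contribution is that matrix's largest eigenvalue).
"""

import itertools

import numpy as np
from scipy.stats import pearsonr


def gev_direct(maps, weights, templates, assignment):
    """Direct-summation GEV: loop over maps, scipy Pearson correlation."""
    maps = np.asarray(maps, dtype=float)
    weights = np.asarray(weights, dtype=float)
    denom = sum(w**2 for w in weights)
    k = templates.shape[0]
    per_class = np.zeros(k)
    for t in range(maps.shape[0]):
        a = assignment[t]
        if a < 0:
            continue
        r = pearsonr(maps[t], templates[a]).statistic
        per_class[a] += (weights[t] * r) ** 2
    return per_class / denom, per_class.sum() / denom


def _unit_mean_zero(maps):
    X = maps - maps.mean(axis=1, keepdims=True)
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def best_partition_gev(maps, weights, n_blocks=3):
    """Maximum GEV over all partitions of the maps into ``n_blocks`` clusters.

    Enumerates every set partition (element 0 pinned to block 1 to kill
    block-order symmetry).  Block contribution = lambda_max of
    sum_t w_t^2 v_t v_t^T over the block, precomputed for all 2^n subsets.
    """
    V = _unit_mean_zero(np.asarray(maps, dtype=float))
    w = np.asarray(weights, dtype=float)
    n, E = V.shape
    denom = float(np.sum(w**2))
    outer = np.einsum("t,te,tf->tef", w**2, V, V)
    # subset-sum matrices by DP over the lowest set bit
    M = np.zeros((1 << n, E, E))
    for s in range(1, 1 << n):
        low = s & -s
        M[s] = M[s ^ low] + outer[low.bit_length() - 1]
    lam = np.zeros(1 << n)
    nz = np.arange(1, 1 << n)
    lam[nz] = np.linalg.eigvalsh(M[nz])[:, -1]

    full = (1 << n) - 1
    best = -np.inf
    if n_blocks != 3:
        raise NotImplementedError("oracle written for 3 blocks")
    for m1 in range(1, full + 1, 2):  # block containing element 0
        rest = full ^ m1
        if rest == 0:
            continue
        # enumerate submasks of rest containing its lowest bit
        low = rest & -rest
        sub = rest
        while sub:
            if sub & low:
                m3 = rest ^ sub
                if m3:
                    total = lam[m1] + lam[sub] + lam[m3]
                    if total > best:
                        best = total
            sub = (sub - 1) & rest
    return best / denom


def welch_direct(a, b):
    """Textbook Welch t statistic, Welch-Satterthwaite df, two-tailed p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def mixed_anova_ss(values, groups):
    """Hand-coded sums-of-squares decomposition for a balanced mixed design.

    values: (n_subjects, n_levels) within-factor observations;
    groups: (n_subjects,) group code.  Returns dict of F and df pairs for
    the between effect, within effect and interaction (uncorrected).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n, p = values.shape
    glevels = np.unique(groups)
    grand = values.mean()
    subj_means = values.mean(axis=1)
    group_means = {g: values[groups == g].mean() for g in glevels}
    level_means = values.mean(axis=0)
    cell_means = {g: values[groups == g].mean(axis=0) for g in glevels}

    ss_group = p * sum(
        (groups == g).sum() * (group_means[g] - grand) ** 2 for g in glevels
    )
    ss_subj = p * sum(
        (subj_means[i] - group_means[groups[i]]) ** 2 for i in range(n)
    )
    ss_within = n * np.sum((level_means - grand) ** 2)
    ss_inter = sum(
        (groups == g).sum()
        * np.sum((cell_means[g] - level_means - group_means[g] + grand) ** 2)
        for g in glevels
    )
    ss_err = sum(
        np.sum(
            (
                values[i]
                - cell_means[groups[i]]
                - subj_means[i]
                + group_means[groups[i]]
            )
            ** 2
        )
        for i in range(n)
    )
    df_group = len(glevels) - 1
    df_subj = n - len(glevels)
    df_within = p - 1
    df_inter = df_group * df_within
    df_err = df_subj * df_within
    return {
        "group": (ss_group / df_group / (ss_subj / df_subj), (df_group, df_subj)),
        "within": (ss_within / df_within / (ss_err / df_err), (df_within, df_err)),
        "interaction": (ss_inter / df_inter / (ss_err / df_err), (df_inter, df_err)),
    }
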