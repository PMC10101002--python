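"""Community-level statistics: filtering, diversity, ordination, tests.

Implements the standard toolkit used on amplicon abundance tables before and
around network construction: prevalence/abundance filtering, Shannon
diversity, Bray-Curtis and (abundance-weighted, Ruzicka) Jaccard
dissimilarities, classical PCoA, multi-factor sequential PERMANOVA, the
Mantel test, and per-taxon differential enrichment between two groups
("volcano plot" style) with Benjamini-Hochberg control.

Permutation p-values use the add-one convention p = (1 + b) / (1 + n_perm),
except in exhaustive mode where all n! orderings (including the identity)
are enumerated and p is the exact tail fraction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import AbundanceTable, MetaboliteTable, SampleMetadata, TableError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# -- filtering -------------------------------------------------------------


def filter_taxa(t: AbundanceTable, min_prevalence: float = 0.20,
                min_mean_ra: float = 1e-4) -> AbundanceTable:
    """Keep taxa present in strictly more than ``min_prevalence`` of samples
    AND with mean relative abundance strictly greater than ``min_mean_ra``.

    Both inequalities are strict, mirroring the conventional ">20% of
    samples" / ">0.01% mean relative abundance" node-selection rule.
    """
    if t.n_taxa == 0 or t.n_samples == 0:
        raise TableError("empty abundance table")
    ra = t.relative_abundance()
    prevalence = (t.counts > 0).sum(axis=1) / t.n_samples
    mean_ra = ra.mean(axis=1)
    keep = (prevalence > min_prevalence) & (mean_ra > min_mean_ra)
    if not keep.any():
        raise TableError(
            "all taxa removed by filtering; relax min_prevalence/min_mean_ra"
        )
    return AbundanceTable(t.counts.loc[keep], t.domain_of.loc[keep],
                          t.is_relative)


# -- diversity -------------------------------------------------------------


def shannon_index(t: AbundanceTable, sample: str,
                  taxa_subset=None) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) for one sample.

    Abundances are renormalized over ``taxa_subset`` (default: all taxa), so
    H measures evenness *within* the subset.  A subset with zero total
    abundance in the sample yields H = 0 with a warning.
    """
    col = t.counts[sample]
    if taxa_subset is not None:
        subset = [x for x in taxa_subset if x in t.counts.index]
        if not subset:
            raise TableError("taxa_subset has no overlap with the table")
        col = col.loc[subset]
    total = float(col.sum())
    if total <= 0:
        warnings.warn(f"zero total abundance in sample {sample!r}; H set to 0")
        return 0.0
    p = col.to_numpy(dtype=float) / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_profile(t: AbundanceTable, taxa_subset=None) -> pd.Series:
    """Shannon index for every sample (vectorized convenience wrapper)."""
    return pd.Series(
        {s: shannon_index(t, s, taxa_subset) for s in t.sample_ids},
        name="shannon",
    )


# -- dissimilarity ---------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    sample_ids: list
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise TableError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise TableError("dissimilarity matrix not symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise TableError("dissimilarity diagonal not zero")
        if (self.D < -1e-12).any() or (self.D > 1 + 1e-9).any():
            raise TableError("dissimilarity entries outside [0, 1]")

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


def _pairwise_dissimilarity(X: np.ndarray, metric: str,
                            abundance_weighted: bool) -> np.ndarray:
    """Square dissimilarity matrix from a samples x taxa matrix."""
    X = np.asarray(X, dtype=float)
    if metric == "bray":
        if abundance_weighted:
            D = squareform(pdist(X, metric="braycurtis"))
        else:
            D = squareform(pdist((X > 0).astype(float), metric="braycurtis"))
    elif metric == "jaccard":
        if abundance_weighted:
            # Ruzicka: 1 - sum(min) / sum(max)
            n = X.shape[0]
            D = np.zeros((n, n))
            for i in range(n):
                mins = np.minimum(X[i], X[i + 1:]).sum(axis=1)
                maxs = np.maximum(X[i], X[i + 1:]).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    d = 1.0 - np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 1.0)
                D[i, i + 1:] = d
                D[i + 1:, i] = d
        else:
            D = squareform(pdist((X > 0), metric="jaccard"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.nan_to_num(D, nan=0.0)


def dissimilarity(t: AbundanceTable, metric: str = "bray",
                  abundance_weighted: bool = True) -> DissimilarityMatrix:
    """Pairwise sample dissimilarities on relative abundances.

    ``bray``: D = sum|x-y| / sum(x+y); ``jaccard`` (weighted) is the Ruzicka
    generalization 1 - sum(min)/sum(max).  With ``abundance_weighted=False``
    both use presence/absence.
    """
    if t.n_samples < 2:
        raise TableError("need at least 2 samples")
    ra = t.relative_abundance()
    if (ra.sum(axis=0) <= 0).any():
        bad = list(ra.columns[ra.sum(axis=0) <= 0])
        raise TableError(f"samples with all-zero abundance: {bad}")
    D = _pairwise_dissimilarity(ra.to_numpy().T, metric, abundance_weighted)
    return DissimilarityMatrix(t.sample_ids, D)


def metabolite_dissimilarity(met: MetaboliteTable, metric: str = "bray") -> DissimilarityMatrix:
    X = met.concentrations.to_numpy().T
    D = _pairwise_dissimilarity(X, metric, abundance_weighted=True)
    return DissimilarityMatrix(met.sample_ids, D)


# -- ordination ------------------------------------------------------------


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # samples x axes
    eigenvalues: np.ndarray          # all eigenvalues, descending (may be <0)
    proportion_explained: np.ndarray  # eig / sum of positive eigs


def pcoa(D: DissimilarityMatrix, k: int = 2) -> PcoaResult:
    """Classical metric scaling of the double-centered -D^2/2 matrix.

    Axes are ordered by eigenvalue; negative eigenvalues are reported as-is
    (no Lingoes/Cailliez correction).  Asking for more axes than the positive
    rank returns all available axes with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(D.sample_ids)
    A = -0.5 * D.D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"requested {k} axes but positive rank is {n_pos}")
        k = max(n_pos, 1)
    coords = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0.0, None))
    pos_sum = eigvals[pos].sum() if n_pos else 1.0
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=list(D.sample_ids),
            columns=[f"PCo{i + 1}" for i in range(k)]),
        eigenvalues=eigvals,
        proportion_explained=eigvals / pos_sum,
    )


# -- PERMANOVA -------------------------------------------------------------


def _gower_matrix(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat_matrix(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    r = np.linalg.matrix_rank(X)
    Q = Q[:, :r]
    return Q @ Q.T


def _dummy(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(list(labels)).astype(str)).to_numpy(float)


def permanova(D: DissimilarityMatrix, factors, n_perm: int = 999,
              seed: int = 0, sequential: bool = True,
              exhaustive: bool = False) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    ``factors`` is a mapping / DataFrame of factor name -> per-sample labels
    (in D's sample order), or a single label sequence.  Effects are
    partitioned sequentially (Type I, adonis convention) in the given order;
    ``sequential=False`` gives marginal effects (each factor adjusted for all
    others).  p-values come from unrestricted permutations of sample
    identity, add-one convention, or from exhaustive enumeration of all n!
    orderings when ``exhaustive`` (only sensible for very small n).

    Returns a DataFrame with one row per factor plus a Residual row;
    sequential R2 values and the residual sum to 1.
    """
    if isinstance(factors, (pd.Series, list, np.ndarray, tuple)):
        factors = {"factor": list(factors)}
    elif isinstance(factors, pd.DataFrame):
        factors = {c: factors[c].tolist() for c in factors.columns}
    n = len(D.sample_ids)
    for name, lab in factors.items():
        if len(lab) != n:
            raise TableError(f"factor {name!r} length != number of samples")
        if len(set(map(str, lab))) < 2:
            raise TableError(f"factor {name!r} has fewer than 2 levels")
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")

    G = _gower_matrix(D.D)
    ss_total = float(np.trace(G))
    names = list(factors)
    dummies = [_dummy(factors[k]) for k in names]
    ones = np.ones((n, 1))

    # hat matrices for nested (sequential) or leave-one-out (marginal) models
    H_cum = [_hat_matrix(ones)]
    for i in range(len(names)):
        X = np.hstack([ones] + dummies[: i + 1])
        H_cum.append(_hat_matrix(X))
    H_full = H_cum[-1]
    df_model = [int(round(np.trace(H_cum[i + 1] - H_cum[i])))
                for i in range(len(names))]
    if sequential:
        effects = [H_cum[i + 1] - H_cum[i] for i in range(len(names))]
    else:
        effects = []
        for i in range(len(names)):
            X_wo = np.hstack([ones] + [d for j, d in enumerate(dummies) if j != i])
            H_wo = _hat_matrix(X_wo)
            effects.append(H_full - H_wo)
            df_model[i] = int(round(np.trace(H_full - H_wo)))
    resid = np.eye(n) - H_full
    df_resid = n - int(round(np.trace(H_full)))
    if df_resid <= 0:
        raise TableError("no residual degrees of freedom")

    def stat_for(Gp):
        ss_eff = np.array([float(np.sum(E * Gp.T)) for E in effects])
        ss_res = float(np.sum(resid * Gp.T))
        F = (ss_eff / np.array(df_model)) / (ss_res / df_resid)
        return ss_eff, ss_res, F

    ss_eff, ss_res, F_obs = stat_for(G)

    if exhaustive:
        count = np.zeros(len(names))
        total = 0
        for perm in itertools.permutations(range(n)):
            Gp = G[np.ix_(perm, perm)]
            _, _, Fp = stat_for(Gp)
            count += Fp >= F_obs - 1e-12
            total += 1
        pvals = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(names))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            _, _, Fp = stat_for(Gp)
            count += Fp >= F_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)

    rows = []
    for i, name in enumerate(names):
        rows.append({"factor": name, "df": df_model[i], "SS": ss_eff[i],
                     "R2": ss_eff[i] / ss_total, "F": F_obs[i], "p": pvals[i]})
    rows.append({"factor": "Residual", "df": df_resid, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("factor")


# -- Mantel ----------------------------------------------------------------


def mantel(D1: DissimilarityMatrix, D2: DissimilarityMatrix,
           method: str = "pearson", n_perm: int = 999, seed: int = 0,
           exhaustive: bool = False) -> dict:
    """Mantel correlation between two distance matrices on the same samples.

    Correlates the lower triangles; significance by permuting the sample
    order of D2 (add-one convention, or exact enumeration of all n!
    orderings when ``exhaustive``).  Two-sided on |r|.
    """
    if list(D1.sample_ids) != list(D2.sample_ids):
        raise TableError("sample sets/order differ between matrices")
    n = len(D1.sample_ids)
    iu = np.triu_indices(n, k=1)

    def flat(M):
        v = M[iu]
        if method == "spearman":
            v = stats.rankdata(v)
        elif method != "pearson":
            raise ValueError(f"unknown method {method!r}")
        return v

    x = flat(D1.D)

    def corr_with(M2):
        y = flat(M2)
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr_with(D2.D)
    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            rp = corr_with(D2.D[np.ix_(perm, perm)])
            count += abs(rp) >= abs(r_obs) - 1e-12
            total += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            rp = corr_with(D2.D[np.ix_(perm, perm)])
            count += abs(rp) >= abs(r_obs) - 1e-12
        p = (1 + count) / (1 + n_perm)
    return {"r": r_obs, "p": float(p), "n_perm": (math.factorial(n)
                                                  if exhaustive else n_perm)}


# -- differential enrichment ----------------------------------------------


def differential_enrichment(t: AbundanceTable, meta: SampleMetadata,
                            group_factor: str | None = None,
                            alpha: float = 0.05, dominance_ra: float = 1e-3,
                            test: str = "wilcoxon") -> pd.DataFrame:
    """Per-taxon two-group enrichment on relative abundances.

    Two-sided Wilcoxon rank-sum by default (``test='ttest'`` for Welch's t),
    BH adjustment across taxa.  ``enriched_in`` is the group with the larger
    mean RA when p_adj <= alpha.  ``log2fc`` uses group means with a
    pseudo-count of half the smallest nonzero RA.  ``dominant`` flags taxa
    with overall mean RA strictly greater than ``dominance_ra``.
    """
    meta.require_samples(t.sample_ids)
    col = group_factor or meta.group_col
    groups = meta.frame.loc[t.sample_ids, col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise TableError(f"need exactly two group levels, got {levels}")
    ga, gb = levels
    na, nb = (groups == ga).sum(), (groups == gb).sum()
    if min(na, nb) < 3:
        raise TableError("each group needs at least 3 samples")

    ra = t.relative_abundance()
    Xa = ra.loc[:, groups[groups == ga].index].to_numpy()
    Xb = ra.loc[:, groups[groups == gb].index].to_numpy()
    nz = ra.to_numpy()
    nz = nz[nz > 0]
    pseudo = 0.5 * (nz.min() if nz.size else 1e-12)

    pvals = np.ones(t.n_taxa)
    for i in range(t.n_taxa):
        a, b = Xa[i], Xb[i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
            continue
        if test == "wilcoxon":
            pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif test == "ttest":
            pvals[i] = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    p_adj = bh_adjust(pvals)
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))
    enriched = np.where(p_adj <= alpha,
                        np.where(log2fc > 0, ga, gb), "none")
    enriched = np.where((p_adj <= alpha) & (log2fc == 0), "none", enriched)
    overall = ra.mean(axis=1).to_numpy()
    out = pd.DataFrame({
        "log2fc": log2fc, "p": pvals, "p_adj": p_adj,
        "enriched_in": enriched, "mean_ra": overall,
        "dominant": overall > dominance_ra,
    }, index=t.taxa_ids)
    out.index.name = "taxon_id"
    return out
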