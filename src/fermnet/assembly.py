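"""Community assembly: Sloan neutral model and normalized stochasticity.

Sloan neutral model
-------------------
Under neutral dynamics with immigration, the long-run relative abundance of
a taxon with metacommunity frequency p in a local community of size N is
Beta(N*m*p, N*m*(1-p)) distributed, where m is the immigration
(migration) rate.  The probability of *detecting* the taxon in a sample at
detection limit d = 1/N is therefore

    f_pred(p; m) = 1 - BetaCDF(d; N*m*p, N*m*(1-p)).

m is estimated by least squares of the observed occurrence frequencies
f_obs on f_pred across taxa, with R^2 = 1 - SSR/SST.  Taxa are partitioned
into "neutral" (f_obs within the 95% band around f_pred), "above" (more
frequent than predicted: favored/widely dispersed) and "below" (less
frequent: locally inhibited or dispersal limited).  The default band is the
Wilson binomial confidence interval of f_pred at the number of samples,
which accounts for the binomial sampling noise of an occurrence frequency
estimated from finitely many samples; a taxon-bootstrap percentile band
(which only reflects uncertainty in m and is much narrower) is available
via ``ci_method="bootstrap"``.  The taxon bootstrap always supplies the CI
for m and R^2.

Normalized stochasticity ratio (NST)
------------------------------------
For each within-group sample pair the observed dissimilarity D_ij is
compared with its expectation E_ij under a null model that preserves each
sample's richness and total abundance while drawing taxon occurrences with
probability proportional to observed occurrence frequency and assigning
abundance proportional to mean relative abundance (proportional-
proportional null).  The per-pair stochasticity ratio is the closeness of
observed to null, ST_ij = (1-E)/(1-D) if D < E else E/D (capped at 1), and
ST is its mean.  NST rescales the per-pair *selection strength*

    SS_ij = (D-E)/(1-E)  if D > E   (divergence beyond null)
          = (E-D)/E      if D < E   (convergence beyond null)

to NST = 1 - mean(SS), so data generated by the null model itself score
~100% and perfectly deterministic data score ~0%; 50% is the conventional
boundary between predominantly deterministic (<50%) and predominantly
stochastic (>50%) assembly.  NST values depend on the null model; the
sampler is exposed (:func:`null_communities`) and seeded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .community_stats import DissimilarityMatrix, _pairwise_dissimilarity
from .tables_io import AbundanceTable, SampleMetadata, TableError


# -- Sloan neutral model ---------------------------------------------------


@dataclass
class NeutralFit:
    m: float
    m_ci: tuple
    N: int
    d: float
    r2: float
    table: pd.DataFrame  # per taxon: p, f_obs, f_pred, lower, upper, partition
    summary: dict        # counts + cumulative relative abundance per partition
    n_boot: int
    seed: int
    ci_method: str


def predicted_frequency(p, m: float, N: int) -> np.ndarray:
    """Sloan detection-frequency curve f_pred = 1 - BetaCDF(1/N; Nmp, Nm(1-p))."""
    p = np.asarray(p, dtype=float)
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(1.0 / N, a, b)


def _fit_m(p: np.ndarray, f_obs: np.ndarray, N: int) -> float:
    def ssr(m):
        return float(np.sum((f_obs - predicted_frequency(p, m, N)) ** 2))

    res = optimize.minimize_scalar(ssr, bounds=(1e-6, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise TableError(f"neutral-model fit failed: {res.message}")
    return float(res.x)


def fit_neutral_model(t: AbundanceTable, n_boot: int = 1000, seed: int = 0,
                      ci_method: str = "wilson",
                      ci_level: float = 0.95) -> NeutralFit:
    """Fit the Sloan neutral model to an integer count table.

    N is the rounded mean sample depth and the detection limit d = 1/N.
    Taxa absent everywhere are excluded before fitting.  The m and R^2 CIs
    come from resampling taxa with replacement and refitting (``n_boot``
    replicates).
    """
    counts = t.counts.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise TableError("fit_neutral_model needs raw integer counts")
    if t.n_samples < 5:
        raise TableError("need at least 5 samples")
    S = t.n_samples
    depth = counts.sum(axis=0)
    N = int(round(depth.mean()))
    d = 1.0 / N
    ra = counts / depth
    p_all = ra.mean(axis=1)
    present = p_all > 0
    if present.sum() < 10:
        raise TableError("need at least 10 taxa present")
    taxa = np.asarray(t.taxa_ids)[present]
    p = p_all[present]
    f_obs = (counts[present] > 0).sum(axis=1) / S

    m_hat = _fit_m(p, f_obs, N)
    f_pred = predicted_frequency(p, m_hat, N)
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    ssr = float(np.sum((f_obs - f_pred) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else -np.inf

    rng = np.random.default_rng(seed)
    n_taxa = p.size
    m_boot = np.empty(n_boot)
    curves = np.empty((n_boot, n_taxa)) if ci_method == "bootstrap" else None
    for b in range(n_boot):
        idx = rng.integers(0, n_taxa, size=n_taxa)
        m_b = _fit_m(p[idx], f_obs[idx], N)
        m_boot[b] = m_b
        if curves is not None:
            curves[b] = predicted_frequency(p, m_b, N)
    alpha = 1.0 - ci_level
    m_ci = tuple(np.quantile(m_boot, [alpha / 2, 1 - alpha / 2]))

    if ci_method == "wilson":
        lower, upper = proportion_confint(f_pred * S, S, alpha=alpha,
                                          method="wilson")
    elif ci_method == "bootstrap":
        lower, upper = np.quantile(curves, [alpha / 2, 1 - alpha / 2], axis=0)
        lower = np.minimum(lower, f_pred)
        upper = np.maximum(upper, f_pred)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    partition = np.where(f_obs > upper, "above",
                         np.where(f_obs < lower, "below", "neutral"))
    table = pd.DataFrame({
        "p": p, "f_obs": f_obs, "f_pred": f_pred,
        "lower": lower, "upper": upper, "partition": partition,
    }, index=taxa)
    table.index.name = "taxon_id"
    total_p = p.sum()
    summary = {}
    for lab in ("neutral", "above", "below"):
        mask = partition == lab
        summary[lab] = {
            "n_taxa": int(mask.sum()),
            "fraction_taxa": float(mask.mean()),
            "cumulative_ra": float(p[mask].sum() / total_p),
        }
    return NeutralFit(m=m_hat, m_ci=m_ci, N=N, d=d, r2=r2, table=table,
                      summary=summary, n_boot=n_boot, seed=seed,
                      ci_method=ci_method)


def simulate_neutral(meta_p, N: int, m: float, n_samples: int, seed: int = 0,
                     taxa_ids=None, sample_ids=None,
                     domain: str = "bacteria") -> AbundanceTable:
    """Sample neutral local communities from a metacommunity.

    Each sample's composition is drawn Dirichlet(N*m*meta_p) -- the
    stationary Sloan/Hubbell local-community distribution, whose marginals
    are the Beta distributions of the detection-frequency formula -- and
    counts are then drawn multinomially at depth N.
    """
    meta_p = np.asarray(meta_p, dtype=float)
    if meta_p.ndim != 1 or (meta_p < 0).any() or not np.isclose(meta_p.sum(), 1.0):
        raise TableError("meta_p must be a probability vector summing to 1")
    if m <= 0:
        raise TableError("migration rate m must be > 0")
    rng = np.random.default_rng(seed)
    alpha = N * m * meta_p
    alpha = np.clip(alpha, 1e-12, None)
    counts = np.empty((meta_p.size, n_samples), dtype=int)
    for j in range(n_samples):
        local = rng.dirichlet(alpha)
        counts[:, j] = rng.multinomial(N, local)
    taxa_ids = taxa_ids if taxa_ids is not None else \
        [f"otu{i}" for i in range(meta_p.size)]
    sample_ids = sample_ids if sample_ids is not None else \
        [f"s{j}" for j in range(n_samples)]
    df = pd.DataFrame(counts, index=taxa_ids, columns=sample_ids)
    return AbundanceTable(df, pd.Series(domain, index=df.index), False)


# -- NST -------------------------------------------------------------------


@dataclass
class NstResult:
    group: str
    metric: str
    abundance_weighted: bool
    n_rand: int
    D_obs: np.ndarray    # condensed observed dissimilarities
    E_null: np.ndarray   # condensed null-mean dissimilarities
    st: float            # stochasticity ratio in [0, 1]
    nst: float           # normalized stochasticity ratio in [0, 1]
    nst_percent: float
    seed: int


def null_communities(counts: np.ndarray, rng: np.random.Generator,
                     freq: np.ndarray | None = None,
                     mean_ra: np.ndarray | None = None) -> np.ndarray:
    """One draw from the proportional-proportional null model.

    Preserves each sample's richness and total count; taxon occurrence is
    drawn (without replacement, Gumbel top-k) with probability proportional
    to observed occurrence frequency; each occurring taxon gets one
    individual and the rest of the sample's depth is multinomial with
    probability proportional to mean relative abundance.
    """
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    depth = counts.sum(axis=0)
    richness = (counts > 0).sum(axis=0)
    if freq is None:
        freq = (counts > 0).mean(axis=1)
    if mean_ra is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_ra = (counts / np.where(depth > 0, depth, 1)).mean(axis=1)
    w = np.where(freq > 0, freq, 0.0)
    logw = np.full(n_taxa, -np.inf)
    logw[w > 0] = np.log(w[w > 0])
    out = np.zeros((n_taxa, n_samples), dtype=float)
    gumbel = rng.gumbel(size=(n_samples, n_taxa))
    for j in range(n_samples):
        r = int(richness[j])
        if r == 0:
            continue
        keys = logw + gumbel[j]
        chosen = np.argpartition(-keys, r - 1)[:r]
        probs = mean_ra[chosen]
        total = probs.sum()
        probs = probs / total if total > 0 else np.full(r, 1.0 / r)
        extra = int(depth[j]) - r
        alloc = np.ones(r)
        if extra > 0:
            alloc += rng.multinomial(extra, probs)
        out[chosen, j] = alloc
    return out


def _st_nst(D: np.ndarray, E: np.ndarray) -> tuple:
    """Per-pair ratios -> (ST, NST) on the [0, 1] scale."""
    D = np.asarray(D, float)
    E = np.asarray(E, float)
    st_pairs = np.empty_like(D)
    ss_pairs = np.empty_like(D)
    for k in range(D.size):
        d, e = D[k], E[k]
        if np.isclose(d, e):
            st_pairs[k] = 1.0
            ss_pairs[k] = 0.0
        elif d < e:  # more similar than null: convergent selection
            st_pairs[k] = (1.0 - e) / (1.0 - d) if d < 1 else 1.0
            ss_pairs[k] = (e - d) / e if e > 0 else 0.0
        else:        # more dissimilar than null: divergent selection
            st_pairs[k] = e / d if d > 0 else 1.0
            ss_pairs[k] = (d - e) / (1.0 - e) if e < 1 else 0.0
    st = float(np.clip(st_pairs, 0, 1).mean())
    nst = float(np.clip(1.0 - np.clip(ss_pairs, 0, 1).mean(), 0, 1))
    return st, nst


def nst(t: AbundanceTable, groups, metric: str = "jaccard",
        abundance_weighted: bool = True, n_rand: int = 1000,
        seed: int = 0) -> dict:
    """Normalized stochasticity ratio per group of samples.

    ``groups`` is a per-sample label Series/mapping (or a SampleMetadata,
    whose group column is used).  Each group needs >= 3 samples.  Returns
    ``{group: NstResult}``; ``nst_percent`` is on the 0-100 scale with 50 as
    the deterministic/stochastic boundary.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if isinstance(groups, SampleMetadata):
        groups.require_samples(t.sample_ids)
        groups = groups.groups(t.sample_ids)
    if isinstance(groups, (list, tuple, np.ndarray)):
        if len(groups) != t.n_samples:
            raise TableError("group labels length != number of samples")
        groups = pd.Series(list(groups), index=t.sample_ids)
    else:
        groups = pd.Series(groups).loc[t.sample_ids]

    results = {}
    ss = np.random.SeedSequence(seed)
    for group, child in zip(sorted(groups.unique().tolist()),
                            ss.spawn(len(groups.unique()))):
        samples = groups.index[groups == group].tolist()
        if len(samples) < 3:
            raise TableError(f"group {group!r} has fewer than 3 samples")
        sub = t.subset_samples(samples)
        counts = sub.counts.to_numpy()
        ra = sub.relative_abundance().to_numpy()
        D_obs = _pairwise_dissimilarity(ra.T, metric, abundance_weighted)
        iu = np.triu_indices(len(samples), k=1)
        d_obs = D_obs[iu]
        if np.allclose(d_obs, 0.0):
            warnings.warn(f"group {group!r}: all samples identical; NST = 0")
        rng = np.random.default_rng(child)
        freq = (counts > 0).mean(axis=1)
        depth = counts.sum(axis=0)
        mean_ra = (counts / np.where(depth > 0, depth, 1)).mean(axis=1)
        e_accum = np.zeros_like(d_obs)
        for _ in range(n_rand):
            null = null_communities(counts, rng, freq=freq, mean_ra=mean_ra)
            null_ra = null / null.sum(axis=0, keepdims=True)
            Dn = _pairwise_dissimilarity(null_ra.T, metric, abundance_weighted)
            e_accum += Dn[iu]
        e_null = e_accum / n_rand
        st, nst_val = _st_nst(d_obs, e_null)
        results[str(group)] = NstResult(
            group=str(group), metric=metric,
            abundance_weighted=abundance_weighted, n_rand=n_rand,
            D_obs=d_obs, E_null=e_null, st=st, nst=nst_val,
            nst_percent=100.0 * nst_val, seed=seed,
        )
    return results


# -- serialization ---------------------------------------------------------


def write_neutral_fit(fit: NeutralFit, path) -> None:
    """JSON scalar summary plus per-taxon partition TSV."""
    path = Path(path)
    payload = {
        "m": fit.m, "m_ci": list(fit.m_ci), "N": fit.N, "d": fit.d,
        "r2": fit.r2, "n_boot": fit.n_boot, "seed": fit.seed,
        "ci_method": fit.ci_method, "summary": fit.summary,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    fit.table.to_csv(path.with_suffix(".taxa.tsv"), sep="\t")
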