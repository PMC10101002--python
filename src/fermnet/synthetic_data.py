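"""Ground-truth synthetic datasets for the whole pipeline.

The generator emulates a paired bacterial/fungal fermentation survey: a
lognormal metacommunity sampled into local communities under Sloan neutral
dynamics (known migration rate), a subset of non-neutral taxa driven by an
environmental covariate (a per-group temperature trajectory), block-
correlated taxa forming plantable network modules with designated connector
nodes, and metabolite vectors that are linear functions of one module's
Shannon diversity plus noise (one metabolite class coupled negatively, one
positively), plus group-indicator metabolites for classifier benchmarks.

Planted-structure geometry.  With an edge threshold of |rho| >= 0.8, the
sum of squared correlations of one variable with mutually orthogonal
factors cannot exceed 1, so a connector node cannot correlate >= 0.8 with
members of three independent blocks: the spanned blocks' factors must
themselves be correlated.  Given a connector axis x with loading c onto
each of s spanned factors, the geometric minimum pairwise factor
correlation is reached when the factors' residuals form a regular simplex
around x (pairwise residual cosine -1/(s-1)); for s = 3 this gives factor
correlation 1.5 c^2 - 0.5.  The generator realizes this geometry *exactly*
in sample space (factors are linear combinations of orthonormalized basis
vectors, so realized correlations equal their targets instead of
fluctuating by ~1/sqrt(n)), which keeps connector-member correlations
(~c, default 0.88) robustly above the edge threshold and between-block
member correlations (~0.63) robustly below it.  A connector must span
three modules because a node whose links split over only two has
participation coefficient Pi <= 0.5, below the 0.62 connector boundary.

Module members, connectors and selected taxa are non-neutral by
construction: their expected abundance is the metacommunity frequency times
the planted multiplier (factor or environmental response), with only
multinomial counting noise on top.  Neutral background taxa go through the
full Dirichlet-multinomial Sloan draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .assembly import null_communities, simulate_neutral
from .community_stats import shannon_profile
from .tables_io import AbundanceTable, MetaboliteTable, SampleMetadata, TableError


@dataclass
class MetaboliteSpec:
    """metabolite = intercept + slope * SDI(linked module) + N(0, sd).

    ``target_r`` calibrates the noise sd so the population correlation with
    the module SDI is approximately the target (the noise sd is
    |slope| * sd(SDI) * sqrt(1/r^2 - 1))."""
    module: int
    slope: float
    intercept: float
    target_r: float = 0.7


@dataclass
class GeneratorConfig:
    # community sizes and sequencing depths
    n_bacteria: int = 500
    n_fungi: int = 100
    depth_bacteria: int = 40_000
    depth_fungi: int = 43_000
    # sample layout: groups x fermentation days x replicates
    groups: tuple = ("A", "B")
    days: tuple = (0, 2, 5, 10, 15, 30)
    n_replicates: int = 4
    # neutral dynamics
    m_true: float = 0.1
    sigma_log: float = 2.0       # lognormal metacommunity spread
    # planted modules (in the bacterial domain)
    n_modules: int = 5
    module_size: int = 12
    n_connectors: int = 3
    connector_span: int = 3      # modules each connector bridges (>= 3)
    factor_sd: float = 1.0
    connector_loading: float = 0.92  # corr of connector axis with each factor
    member_noise_sd: float = 0.15
    connector_noise_sd: float = 0.08
    module_member_mean_ra: float = 4e-3
    # environmental selection
    selected_fraction: float = 0.05
    selection_slope_mean: float = 1.2
    selection_noise_sd: float = 0.8
    # metabolites
    metabolite_specs: dict = field(default_factory=lambda: {
        "ethyl_acetate": MetaboliteSpec(module=0, slope=-1.5, intercept=8.0),
        "higher_alcohols": MetaboliteSpec(module=0, slope=2.0, intercept=2.0),
    })
    n_indicator_metabolites: int = 4
    indicator_effect_sd: float = 1.5   # per-metabolite group shift, within-sd units
    n_noise_metabolites: int = 24
    # uninformative metabolites co-vary in classes (esters, acids, ...) via
    # shared latent sample factors, as real flavor panels do
    noise_metabolite_latent_factors: int = 3
    noise_metabolite_loading: float = 0.8
    noise_metabolite_noise_sd: float = 0.6

    def n_samples(self) -> int:
        return len(self.groups) * len(self.days) * self.n_replicates


@dataclass
class SyntheticTruth:
    m_true: float
    meta_p: dict                  # domain -> Series taxon -> metacommunity RA
    module_assignment: dict       # member taxon -> planted module id
    connectors: dict              # connector taxon -> tuple of module ids
    selected: dict                # taxon -> environmental response slope
    metabolite_model: dict        # metabolite -> MetaboliteSpec
    indicator_metabolites: list
    env: pd.Series                # z-scored covariate per sample
    seed: int


@dataclass
class SyntheticDataset:
    bacteria: AbundanceTable
    fungi: AbundanceTable
    metabolites: MetaboliteTable
    metadata: SampleMetadata
    truth: SyntheticTruth


def _sample_layout(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for g in cfg.groups:
        for day in cfg.days:
            for r in range(cfg.n_replicates):
                rows.append({"sample_id": f"{g}_d{day}_r{r}",
                             "group": g, "time": day, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def _module_factors(cfg: GeneratorConfig, n_samples: int,
                    rng: np.random.Generator) -> tuple:
    """Latent module factors plus the connector axis, exact in sample space.

    Returns ``(F, x)`` where F is (n_modules, n_samples) and x is the
    connector signal.  Factors are built from orthonormalized Gaussian
    basis vectors, so the *sample* correlations equal the designed ones:
    corr(x, F_m) = connector_loading for the first ``connector_span``
    modules (their residuals sit on a regular simplex around x, minimizing
    their mutual correlation), and 0 for the remaining, mutually orthogonal
    modules.
    """
    s = max(cfg.connector_span, 1)
    k = max(cfg.n_modules, s)
    Z = rng.standard_normal((n_samples, k + 2))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    Q = Q[:, :k] * np.sqrt(n_samples)  # mean-zero, unit sample variance
    x = Q[:, 0]
    c = cfg.connector_loading
    # simplex directions in the (s-1)-dim space orthogonal to x
    V = np.eye(s) - 1.0 / s
    evals, evecs = np.linalg.eigh(V)
    P = evecs[:, -(s - 1):] * np.sqrt(np.clip(evals[-(s - 1):], 0, None))
    P = P / np.linalg.norm(P, axis=1, keepdims=True)
    F = np.empty((cfg.n_modules, n_samples))
    for m in range(cfg.n_modules):
        if m < s:
            u = P[m] @ Q[:, 1:s].T
            F[m] = c * x + np.sqrt(1 - c ** 2) * u
        else:
            F[m] = Q[:, m]
    return F * cfg.factor_sd, x * cfg.factor_sd


def generate_dataset(config: GeneratorConfig | None = None,
                     seed: int = 1) -> SyntheticDataset:
    """Generate one full synthetic dataset with stored ground truth."""
    cfg = config or GeneratorConfig()
    if cfg.connector_span < 3 and cfg.n_connectors > 0:
        raise TableError(
            "connector_span must be >= 3: a node spanning two modules has "
            "Pi <= 0.5 and can never reach the 0.62 connector threshold")
    if cfg.n_connectors > 0 and cfg.connector_span > cfg.n_modules:
        raise TableError("connector_span exceeds the number of modules")
    n_structured = cfg.n_modules * cfg.module_size + cfg.n_connectors
    if n_structured > cfg.n_bacteria:
        raise TableError("not enough bacterial taxa for the module plan")

    ss = np.random.SeedSequence(seed)
    rng_struct, rng_bact, rng_fungi, rng_met = [
        np.random.default_rng(c) for c in ss.spawn(4)]

    layout = _sample_layout(cfg)
    samples = list(layout.index)
    n_samples = len(samples)

    # environmental covariate: warming trajectory + group offset
    temp = (20.0 + 12.0 * layout["time"].to_numpy() / max(cfg.days)
            + 3.0 * (layout["group"] == cfg.groups[-1]).to_numpy()
            + 0.5 * rng_struct.standard_normal(n_samples))
    z_env = (temp - temp.mean()) / temp.std()
    layout["temperature"] = temp

    F, connector_axis = _module_factors(cfg, n_samples, rng_struct)

    tables = {}
    truth_meta_p = {}
    module_assignment: dict = {}
    connectors: dict = {}
    selected: dict = {}
    for domain, n_taxa, depth, rng in (
            ("bacteria", cfg.n_bacteria, cfg.depth_bacteria, rng_bact),
            ("fungi", cfg.n_fungi, cfg.depth_fungi, rng_fungi)):
        prefix = "b" if domain == "bacteria" else "f"
        taxa = [f"{prefix}_otu{i}" for i in range(n_taxa)]
        weights = rng.lognormal(mean=0.0, sigma=cfg.sigma_log, size=n_taxa)

        member_idx = np.array([], dtype=int)
        connector_idx = np.array([], dtype=int)
        if domain == "bacteria" and cfg.n_modules > 0:
            member_idx = np.arange(cfg.n_modules * cfg.module_size)
            connector_idx = np.arange(len(member_idx),
                                      len(member_idx) + cfg.n_connectors)
            structured = np.concatenate([member_idx, connector_idx])
            # pin structured taxa at a moderate metacommunity abundance so
            # counting noise does not swamp the planted correlations
            w_bg = weights.sum()
            weights[structured] = (cfg.module_member_mean_ra * w_bg
                                   * rng.lognormal(0.0, 0.3, structured.size))
            for k, i in enumerate(member_idx):
                module_assignment[taxa[i]] = k // cfg.module_size
            span = tuple(range(cfg.connector_span))
            for i in connector_idx:
                connectors[taxa[i]] = span

        meta_p = weights / weights.sum()
        truth_meta_p[domain] = pd.Series(meta_p, index=taxa)

        structured_set = set(member_idx.tolist()) | set(connector_idx.tolist())
        free = [i for i in range(n_taxa) if i not in structured_set]
        n_sel = int(round(cfg.selected_fraction * n_taxa))
        sel_idx = rng.choice(free, size=min(n_sel, len(free)), replace=False)
        slopes = (rng.choice([-1.0, 1.0], size=sel_idx.size)
                  * rng.normal(cfg.selection_slope_mean, 0.3, sel_idx.size))
        for i, s in zip(sel_idx, slopes):
            selected[taxa[i]] = float(s)

        neutral_idx = np.array(
            sorted(set(range(n_taxa)) - structured_set - set(sel_idx.tolist())),
            dtype=int)

        counts = np.zeros((n_taxa, n_samples), dtype=int)
        alpha_neutral = np.clip(
            depth * cfg.m_true * meta_p[neutral_idx], 1e-12, None)
        sel_pos = {int(i): float(s) for i, s in zip(sel_idx, slopes)}
        for j in range(n_samples):
            w = meta_p.copy()
            if neutral_idx.size:
                x = rng.dirichlet(alpha_neutral)
                w[neutral_idx] = x * meta_p[neutral_idx].sum()
            for k, i in enumerate(member_idx):
                mod = k // cfg.module_size
                w[i] = meta_p[i] * np.exp(
                    F[mod, j] + rng.normal(0.0, cfg.member_noise_sd))
            for i in connector_idx:
                w[i] = meta_p[i] * np.exp(
                    connector_axis[j]
                    + rng.normal(0.0, cfg.connector_noise_sd))
            for i, s in sel_pos.items():
                w[i] = meta_p[i] * np.exp(
                    s * z_env[j] + rng.normal(0.0, cfg.selection_noise_sd))
            w = w / w.sum()
            counts[:, j] = rng.multinomial(depth, w)
        df = pd.DataFrame(counts, index=taxa, columns=samples)
        tables[domain] = AbundanceTable(
            df, pd.Series(domain, index=df.index), False)

    # -- metabolites -------------------------------------------------------
    bact = tables["bacteria"]
    met_rows = {}
    model = {}
    module_members_by_id: dict = {}
    for taxon, mod in module_assignment.items():
        module_members_by_id.setdefault(mod, []).append(taxon)
    for name, spec in cfg.metabolite_specs.items():
        members = module_members_by_id.get(spec.module, [])
        if members:
            sdi = shannon_profile(bact, members).loc[samples].to_numpy()
        else:
            sdi = np.zeros(n_samples)
        sd_sdi = sdi.std()
        if sd_sdi > 0:
            noise_sd = (abs(spec.slope) * sd_sdi
                        * np.sqrt(1.0 / spec.target_r ** 2 - 1.0))
        else:
            noise_sd = 0.1
        vals = (spec.intercept + spec.slope * sdi
                + rng_met.normal(0.0, noise_sd, n_samples))
        met_rows[name] = np.maximum(vals, 0.0)
        model[name] = spec
    indicator_names = [f"indicator_{i}" for i in
                       range(cfg.n_indicator_metabolites)]
    is_last_group = (layout["group"] == cfg.groups[-1]).to_numpy()
    for name in indicator_names:
        vals = (10.0 + cfg.indicator_effect_sd * is_last_group
                + rng_met.normal(0.0, 1.0, n_samples))
        met_rows[name] = np.maximum(vals, 0.0)
    n_latent = max(cfg.noise_metabolite_latent_factors, 1)
    latent = rng_met.standard_normal((n_latent, n_samples))
    for i in range(cfg.n_noise_metabolites):
        g = latent[i % n_latent]
        met_rows[f"noise_{i}"] = np.exp(
            1.5 + cfg.noise_metabolite_loading * g
            + rng_met.normal(0.0, cfg.noise_metabolite_noise_sd, n_samples))
    metabolites = MetaboliteTable(
        pd.DataFrame(met_rows, index=samples).T, unit="mg/kg")

    truth = SyntheticTruth(
        m_true=cfg.m_true, meta_p=truth_meta_p,
        module_assignment=module_assignment, connectors=connectors,
        selected=selected, metabolite_model=model,
        indicator_metabolites=indicator_names,
        env=pd.Series(z_env, index=samples, name="z_temperature"),
        seed=seed,
    )
    return SyntheticDataset(
        bacteria=tables["bacteria"], fungi=tables["fungi"],
        metabolites=metabolites,
        metadata=SampleMetadata(layout), truth=truth,
    )


# -- auxiliary simulators for assembly benchmarks --------------------------


def simulate_null_dataset(n_taxa: int = 300, n_samples: int = 12,
                          depth: int = 10_000, seed: int = 0,
                          m: float = 0.1,
                          sigma_log: float = 1.0) -> AbundanceTable:
    """A dataset drawn from the NST null model itself.

    A neutral parent community supplies the occurrence-frequency and
    mean-abundance constraints; the returned table is one
    proportional-proportional null realization *per sample* of that parent,
    so its NST should sit near 100%.  The per-pair NST contrasts a single
    observed dissimilarity with the null mean, so the reading approaches
    100% only when pairwise dissimilarities concentrate -- hence the
    moderately rich, moderately even default community (300 taxa,
    lognormal sd 1).
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    rng = np.random.default_rng(s2)
    meta_w = np.random.default_rng(s1).lognormal(0.0, sigma_log, n_taxa)
    meta_p = meta_w / meta_w.sum()
    parent = simulate_neutral(meta_p, depth, m, n_samples,
                              seed=int(s1.generate_state(1)[0] % 2 ** 31))
    null = null_communities(parent.counts.to_numpy(), rng)
    df = pd.DataFrame(null.astype(int), index=parent.counts.index,
                      columns=parent.counts.columns)
    return AbundanceTable(df, parent.domain_of, False)


def simulate_selected_dataset(n_taxa: int = 300, n_samples: int = 12,
                              depth: int = 10_000, seed: int = 0,
                              n_clusters: int = 2,
                              within_noise: float = 0.05,
                              sigma_log: float = 1.0,
                              support_fraction: float = 0.6) -> AbundanceTable:
    """Strongly deterministic communities: two (or more) environmental
    optima, each selecting its own (partially overlapping) taxon pool and
    drawing near-identical samples.  Within-cluster pairs are far more
    similar, and between-cluster pairs far less similar, than the pooled
    null expectation, so NST falls below 50%."""
    rng = np.random.default_rng(seed)
    templates = rng.lognormal(0.0, sigma_log, (n_clusters, n_taxa))
    for k in range(n_clusters):  # each optimum admits only part of the pool
        absent = rng.choice(n_taxa, size=int((1 - support_fraction) * n_taxa),
                            replace=False)
        templates[k, absent] = 0.0
    counts = np.empty((n_taxa, n_samples), dtype=int)
    for j in range(n_samples):
        w = (templates[j % n_clusters]
             * np.exp(rng.normal(0.0, within_noise, n_taxa)))
        counts[:, j] = rng.multinomial(depth, w / w.sum())
    df = pd.DataFrame(counts, index=[f"otu{i}" for i in range(n_taxa)],
                      columns=[f"s{j}" for j in range(n_samples)])
    return AbundanceTable(df, pd.Series("bacteria", index=df.index), False)


# -- recovery scoring ------------------------------------------------------


def _precision_recall(predicted, truth) -> dict:
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    return {
        "precision": tp / len(predicted) if predicted else 1.0,
        "recall": tp / len(truth) if truth else 1.0,
        "tp": tp, "fp": len(predicted - truth), "fn": len(truth - predicted),
    }


def truth_report(truth: SyntheticTruth, results: dict) -> dict:
    """Score pipeline outputs against the planted ground truth.

    ``results`` may contain any of: ``partition`` (node -> module id, scored
    by ARI over pure planted block members; connectors bridge several blocks
    by design and are scored separately), ``connectors`` (list),
    ``enriched`` (list), ``indicators`` (list), ``m`` (float), ``slopes``
    (metabolite -> fitted slope).
    """
    report: dict = {}
    if "partition" in results:
        part = results["partition"]
        shared = [x for x in truth.module_assignment if x in part]
        if not shared:
            raise TableError("no planted taxa found in the partition")
        report["module_ari"] = float(adjusted_rand_score(
            [truth.module_assignment[x] for x in shared],
            [part[x] for x in shared]))
        report["module_n_scored"] = len(shared)
    if "connectors" in results:
        report["connector"] = _precision_recall(
            results["connectors"], truth.connectors)
    if "enriched" in results:
        report["enriched"] = _precision_recall(
            results["enriched"], truth.selected)
    if "indicators" in results:
        report["indicator"] = _precision_recall(
            results["indicators"], truth.indicator_metabolites)
    if "m" in results:
        report["m_error"] = float(abs(results["m"] - truth.m_true))
        report["m_relative_error"] = float(
            abs(results["m"] - truth.m_true) / truth.m_true)
    if "slopes" in results:
        report["slope_errors"] = {
            name: float(abs(results["slopes"][name]
                            - truth.metabolite_model[name].slope))
            for name in results["slopes"] if name in truth.metabolite_model}
    return report
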