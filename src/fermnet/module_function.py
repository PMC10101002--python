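"""Linking ecological clusters (network modules) to metabolite profiles.

For every module m and sample j we compute the Shannon diversity SDI_mj of
the module's member taxa (abundances renormalized within the module, so SDI
measures the module's internal evenness, not its total abundance) and the
module's summed relative abundance RA_mj with a per-module z-score across
samples.  Metabolite concentrations are then regressed on either predictor
by ordinary least squares, one fit per (module, metabolite) pair, with BH
adjustment of the slope p-values across all pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import bh_adjust, shannon_index
from .network import CooccurrenceNetwork
from .tables_io import AbundanceTable, MetaboliteTable, TableError

HIGHER_ALCOHOLS = ("isoamyl_alcohol", "phenethyl_alcohol", "isobutanol")


@dataclass
class ModuleProfile:
    sdi: pd.DataFrame        # modules x samples, Shannon in nats
    ra: pd.DataFrame         # modules x samples, summed relative abundance
    ra_z: pd.DataFrame       # ra z-scored per module across samples
    members: dict            # module id -> list of member taxa


def module_profiles(t: AbundanceTable, net: CooccurrenceNetwork) -> ModuleProfile:
    """Per-module, per-sample SDI and (z-scored) summed relative abundance."""
    members = net.module_members()
    missing = [v for mod in members.values() for v in mod
               if v not in t.counts.index]
    if missing:
        raise TableError(f"network taxa absent from table: {missing[:5]}")
    ra = t.relative_abundance()
    samples = t.sample_ids
    sdi_rows, ra_rows = {}, {}
    for mod, taxa in sorted(members.items()):
        block = ra.loc[taxa]
        if (block.sum(axis=1) == 0).all():
            warnings.warn(f"module {mod} has zero abundance everywhere")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sdi_rows[mod] = [shannon_index(t, s, taxa) for s in samples]
        ra_rows[mod] = block.sum(axis=0).to_numpy()
    sdi = pd.DataFrame(sdi_rows, index=samples).T
    ra_sum = pd.DataFrame(ra_rows, index=samples).T
    mu = ra_sum.mean(axis=1)
    sd = ra_sum.std(axis=1, ddof=0).replace(0.0, np.nan)
    ra_z = ra_sum.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return ModuleProfile(sdi=sdi, ra=ra_sum, ra_z=ra_z,
                         members={m: list(v) for m, v in sorted(members.items())})


def diversity_metabolite_regression(mp: ModuleProfile, met: MetaboliteTable,
                                    predictor: str = "SDI",
                                    modules=None) -> pd.DataFrame:
    """OLS of each metabolite on each module's SDI (or z-scored RA).

    Returns one row per (module, metabolite): slope, intercept, r, two-sided
    slope p, BH-adjusted p, and the 95% CI of the slope.  Pairs with a
    constant predictor are skipped with a warning.
    """
    if predictor == "SDI":
        pred = mp.sdi
    elif predictor in ("RA_z", "RA"):
        pred = mp.ra_z if predictor == "RA_z" else mp.ra
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    shared = [s for s in pred.columns if s in met.concentrations.columns]
    if len(shared) < 4:
        raise TableError("need at least 4 shared samples for regression")
    pred = pred[shared]
    conc = met.concentrations[shared]

    rows = []
    mods = list(pred.index) if modules is None else list(modules)
    for mod in mods:
        x = pred.loc[mod].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"module {mod}: constant predictor, skipped")
            continue
        for metab in conc.index:
            y = conc.loc[metab].to_numpy(dtype=float)
            res = stats.linregress(x, y)
            dof = len(x) - 2
            tcrit = stats.t.ppf(0.975, dof)
            rows.append({
                "module": mod, "metabolite": metab,
                "slope": res.slope, "intercept": res.intercept,
                "r": res.rvalue, "p": res.pvalue,
                "slope_ci_low": res.slope - tcrit * res.stderr,
                "slope_ci_high": res.slope + tcrit * res.stderr,
                "n": len(x),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def aggregate_metabolites(met: MetaboliteTable,
                          aliases: dict | None = None) -> MetaboliteTable:
    """Add class-sum rows (e.g. higher alcohols) defined by an alias map.

    ``aliases`` maps a new row name to the component metabolite names; only
    classes whose components all exist are added.  By default adds a
    ``higher_alcohols`` row summing isoamyl alcohol, phenethyl alcohol and
    isobutanol when those columns exist.
    """
    aliases = aliases if aliases is not None else {
        "higher_alcohols": list(HIGHER_ALCOHOLS)}
    conc = met.concentrations.copy()
    for name, parts in aliases.items():
        if name in conc.index:
            continue
        if all(p in conc.index for p in parts):
            conc.loc[name] = conc.loc[parts].sum(axis=0)
    return MetaboliteTable(conc, unit=met.unit)
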