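"""Reproducible simulation studies: parameter recovery and null calibration.

These drivers run the full pipeline end to end on freshly generated synthetic
surveys and measure whether the planted effects are recovered:

* keystone relative abundance falls with pH,
* community mean rrn copy number (MCN) rises with pH,
* positive cohesion tracks keystone abundance,
* removing the keystone from the equilibrium co-occurrence network
  extinguishes more nodes than removing a random single node,
* the comammox supplier share of cobalamin-synthesis abundance falls with pH,
* the 13C label shift in SIP profiles is detected.

Null-calibration drivers check that cohesion is centred at zero on
structure-free communities and that the correlation test holds its nominal
type-I error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import cohesion as coh
from . import envstats, screen, sip
from .network import build_network, correlation_matrix, prevalence_filter
from .robustness import (
    equilibrium_network,
    mean_abundances,
    random_removal_curve,
    simulate_removal_cascade,
)
from .simulate import (
    CommunitySpec,
    generate_community,
    generate_genome_features,
    generate_guild_amoa,
    generate_metadata,
    generate_sip_profiles,
    linear_copies,
)
from .cobalamin import classify_cd_cs, supply_demand_summary
from .tables import AbundanceTable, to_relative


def run_single_recovery(spec: CommunitySpec, cohesion_iters: int = 100) -> dict:
    """One end-to-end pipeline pass on one synthetic survey.

    Returns the per-seed recovery measurements; see :func:`recovery_study`.
    """
    meta = generate_metadata(spec)
    table, truth = generate_community(spec, meta)
    rel = to_relative(table).counts
    key = truth.keystone_id
    ph = meta["pH"].to_numpy()

    out = {"seed": spec.seed}

    # (a) keystone abundance vs pH
    ck = envstats.correlate(rel.loc[key].to_numpy(), ph)
    out["keystone_r"], out["keystone_p"] = ck["r"], ck["p"]

    # (b) MCN vs pH
    mcn = screen.compute_mcn(table, pd.Series(truth.rrn_map))
    out["mcn_r"] = envstats.correlate(mcn.to_numpy(), ph)["r"]

    # (c) positive cohesion vs keystone abundance
    res = coh.cohesion_pipeline(table, n_iter=cohesion_iters, seed=spec.seed)
    out["cohesion_r"] = envstats.correlate(
        res.cohesion["cohesion_pos"].to_numpy(), rel.loc[key].to_numpy()
    )["r"]

    # (d) targeted keystone vs random single-node removal, from the
    # equilibrium network at the fixed default threshold
    filt = prevalence_filter(table, 0.5)
    r = correlation_matrix(filt)
    g0 = build_network(r, spec.network_threshold)
    ab = mean_abundances(filt)
    g = equilibrium_network(g0, ab)
    if key in g:
        targ = simulate_removal_cascade(g, ab, {key})
        curve = random_removal_curve(
            g, ab, [1.0 / g.number_of_nodes()], n_rep=20, seed=spec.seed
        )
        out["targeted_surviving"] = targ.surviving_frac
        out["random_surviving"] = float(curve["mean_surviving"].iloc[0])
    else:
        out["targeted_surviving"] = np.nan
        out["random_surviving"] = np.nan

    # (e) supplier share of the cobalamin-synthesis pool vs pH
    genomes = generate_genome_features(spec, truth, community=table)
    summary = supply_demand_summary(genomes, meta)
    share = summary["supplier_share"].to_numpy()
    ok = np.isfinite(share)
    if ok.sum() >= 4 and np.std(share[ok]) > 0:
        out["supplier_r"] = envstats.correlate(share[ok], ph[ok])["r"]
    else:
        out["supplier_r"] = np.nan
    cls = classify_cd_cs(genomes)
    out["cd_fraction"] = float(cls["is_CD"].mean())

    # (f) SIP label-shift detection for the comammox guild
    tidy = generate_sip_profiles(spec, truth)
    profs = sip.profiles_from_tidy(tidy)
    lab = sip.mean_profile(
        [p for (tr, gl, _), p in profs.items() if tr == "13C" and gl == "comammox"]
    )
    ctl = sip.mean_profile(
        [p for (tr, gl, _), p in profs.items() if tr == "12C" and gl == "comammox"]
    )
    det = sip.detect_label_shift(lab, ctl, min_shift=0.005)
    out["sip_shift"] = det["shift"]
    out["sip_detected"] = det["is_labeled"]

    # dominance of comammox among ammonia oxidizers (guild qPCR table)
    copies = linear_copies(generate_guild_amoa(meta, spec, truth, table))
    dom = screen.classify_dominant_oxidizer(copies)
    out["dominant_comammox_frac"] = float((dom["label"] == "comammox").mean())
    return out


def recovery_study(
    n_seeds: int = 50,
    base_seed: int = 0,
    cohesion_iters: int = 100,
    **spec_kwargs,
) -> pd.DataFrame:
    """Run :func:`run_single_recovery` over ``n_seeds`` independent surveys."""
    rows = []
    for k in range(n_seeds):
        spec = CommunitySpec(seed=int(base_seed) + k, **spec_kwargs)
        rows.append(run_single_recovery(spec, cohesion_iters=cohesion_iters))
    return pd.DataFrame(rows).set_index("seed")


def recovery_rates(study: pd.DataFrame) -> dict:
    """Fraction of seeds recovering each planted effect."""
    targ_ok = study["targeted_surviving"] < study["random_surviving"]
    return {
        "keystone_ph_negative": float(
            ((study["keystone_r"] < 0) & (study["keystone_p"] < 0.05)).mean()
        ),
        "mcn_ph_positive": float((study["mcn_r"] > 0.6).mean()),
        "cohesion_keystone_positive": float((study["cohesion_r"] > 0.5).mean()),
        "targeted_beats_random": float(targ_ok.mean()),
        "supplier_share_declines": float((study["supplier_r"] < -0.4).mean()),
        "sip_label_detected": float(study["sip_detected"].mean()),
    }


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def structureless_table(n_taxa: int = 100, n_samples: int = 40,
                        depth: int = 20_000, seed: int = 0,
                        latent_sd: float = 0.5) -> AbundanceTable:
    """Community with no planted structure: i.i.d. lognormal latents.

    The default ``latent_sd`` keeps abundances moderately even: with very
    heavy-tailed abundances the null distribution of Pearson correlations is
    right-skewed (spike-sharing), which offsets positive/negative
    connectedness means even for perfectly independent taxa and would
    confound a calibration meant to detect estimator bias.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(0.0, latent_sd, (n_taxa, n_samples))
    probs = np.exp(latent)
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depth, probs[:, s])
    idx = pd.Index([f"T{i + 1:04d}" for i in range(n_taxa)], name="taxon_id")
    cols = [f"S{i + 1:02d}" for i in range(n_samples)]
    return AbundanceTable(pd.DataFrame(counts, index=idx, columns=cols))


def taxa_shuffled(table: AbundanceTable, seed: int = 0) -> AbundanceTable:
    """Independently permute each taxon's abundances across samples.

    Shuffling destroys all between-taxon alignment -- including the shared
    sampling-depth denominator that makes even unstructured compositional
    tables weakly positively correlated -- so cohesion on a shuffled table is
    the statistic's true null.
    """
    rng = np.random.default_rng(seed)
    rel = to_relative(table).counts.to_numpy()
    idx = rng.random(rel.shape).argsort(axis=1)
    shuf = np.take_along_axis(rel, idx, axis=1)
    return AbundanceTable(
        pd.DataFrame(shuf, index=table.taxa, columns=table.samples),
        table.taxonomy.copy(),
    )


def cohesion_null_calibration(
    n_taxa: int = 100,
    n_samples: int = 40,
    n_iter: int = 200,
    seed: int = 0,
    n_replicates: int = 8,
) -> dict:
    """Net cohesion on taxa-shuffled (fully independent) data centres at zero.

    Per replicate table the sample cohesions share one connectedness vector,
    so the median's Monte-Carlo variability must be estimated *between*
    replicate null communities: the returned ``mc_se`` is the SE of the mean
    of the per-replicate medians.
    """
    medians = []
    pos_medians = []
    for k in range(n_replicates):
        s = seed + 1000 * k
        table = taxa_shuffled(structureless_table(n_taxa, n_samples, seed=s), seed=s)
        res = coh.cohesion_pipeline(table, n_iter=n_iter, seed=s)
        medians.append(float(np.median(res.cohesion["cohesion_net"])))
        pos_medians.append(float(np.median(res.cohesion["cohesion_pos"])))
    medians = np.asarray(medians)
    return {
        # central tendency of the replicate medians and the MC resolution of
        # a single calibration replicate (the SD of its median); the net
        # median is "centred at zero" when it is below that resolution
        "median_net_cohesion": float(medians.mean()),
        "mc_se": float(medians.std(ddof=1)),
        "se_of_mean": float(medians.std(ddof=1) / np.sqrt(n_replicates)),
        "replicate_medians": medians.tolist(),
        "median_pos": float(np.median(pos_medians)),
    }


def correlate_type1_error(
    n_rep: int = 1000, n: int = 36, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of :func:`acidonet.correlate` on independent data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if envstats.correlate(x, y)["p"] <= alpha:
            hits += 1
    return hits / n_rep
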