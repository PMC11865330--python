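"""Synthetic pH-gradient soil communities with planted ecological structure.

The generator emulates the statistical design the downstream analyses assume:
a soil survey across a wide pH gradient (default 4.4-9.7, 36 samples, groups
A/B/C by pH), with

* a planted "comammox-like" keystone taxon whose abundance falls with pH,
* a cooperation block of taxa co-varying positively with the keystone,
* taxon rrn copy numbers tied to pH preference (acid-favoured taxa carry
  few operons, i.e. slow growers),
* guild-level amoA copy numbers (AOA / AOB / comammox) where only the
  comammox guild trends with pH,
* genome feature tables with widespread cobalamin dependence but rare,
  keystone-concentrated synthesis capacity,
* DNA-SIP density profiles whose peaks shift to heavier fractions when a
  guild assimilates the labelled substrate.

Every artifact draws from its own random stream derived from the master seed
by a labelled child seed, so adding one output never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import AbundanceTable, RrnLookup, RANKS

GUILDS = ("AOA", "AOB", "comammox")

# pH-group boundaries used throughout: A acidic, B neutral, C alkaline
GROUP_A_MAX = 6.5  # group A: pH < 6.5
GROUP_B_MAX = 7.5  # group B: 6.5 <= pH <= 7.5; group C: pH > 7.5


def ph_group(ph: float) -> str:
    """Assign the A/B/C pH group label for a single pH value."""
    if ph < GROUP_A_MAX:
        return "A"
    if ph <= GROUP_B_MAX:
        return "B"
    return "C"


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic survey.

    Defaults mirror the study scale this generator emulates: 36 samples over
    pH 4.4-9.7, ~20k reads per sample, a keystone whose relative abundance
    correlates with pH at about -0.6, and a 12-taxon cooperation block.
    """

    n_samples: int = 36
    n_taxa: int = 100
    ph_range: tuple = (4.4, 9.7)
    keystone_ph_slope: float = -0.6
    coop_block_size: int = 12
    noise_sd: float = 0.5
    sequencing_depth: int = 20_000
    seed: int = 0

    # community fine structure
    baseline_sd: float = 0.8          # spread of taxon mean log-abundances
    keystone_baseline: float = 1.5    # keystone is an abundant (~3%) taxon
    block_baseline: float = 0.3       # cooperation-block taxa moderately abundant
    ph_loading_sd: float = 0.1        # per-taxon pH response (log units / pH unit)
    block_keystone_r: float = 0.70    # target latent corr(block taxon, keystone)
    rrn_loading_slope: float = 2.0    # rrn copies per sd of pH loading
    network_threshold: float = 0.60   # default fixed |r| cutoff at this scale

    # guild qPCR table (log10 copies per g dry soil)
    guild_base_log10: tuple = (("AOA", 7.0), ("AOB", 6.6), ("comammox", 7.6))
    comammox_ph_effect: float = -0.5  # log10 copies per pH unit
    guild_noise_sd: float = 0.25

    # genome feature table
    n_genomes: int = 150
    cd_prevalence: float = 0.85       # P(genome encodes >=1 dependence gene)
    cs_prevalence: float = 0.03       # P(non-keystone genome has full synthesis)
    partial_bc_prevalence: float = 0.12  # genomes with only steps B+C
    genome_level_sd: float = 1.0      # spread of genome-specific abundance levels
    genome_jitter_sd: float = 0.2     # per-sample coverage jitter around the level

    # SIP microcosms
    n_fractions: int = 16
    density_range: tuple = (1.69, 1.76)
    peak_center: float = 1.715        # unlabelled DNA buoyant density peak
    peak_sd: float = 0.012
    planted_shift: float = 0.01       # g/mL shift of labelled active guilds
    sip_replicates: int = 3
    guild_sip_amplitude: tuple = (("comammox", 60_000.0), ("AOA", 25_000.0), ("AOB", 15_000.0))
    active_guilds: tuple = ("comammox", "AOA")
    sip_noise: bool = True

    def __post_init__(self):
        if self.n_samples < 6:
            raise ValueError("n_samples must be >= 6 (correlations degenerate below)")
        lo, hi = self.ph_range
        if not (0 <= lo < hi <= 14):
            raise ValueError("ph_range must be an increasing pair within [0, 14]")
        if not 0 <= self.coop_block_size < self.n_taxa:
            raise ValueError("coop_block_size must be < n_taxa")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.planted_shift < 0:
            raise ValueError("planted_shift must be >= 0")
        if self.n_fractions < 10:
            raise ValueError("need >= 10 density fractions")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for recovery tests."""

    keystone_id: str
    coop_block_ids: list
    rrn_map: dict
    cs_genome_ids: list = field(default_factory=list)
    cd_genome_ids: list = field(default_factory=list)
    planted_shift: float = 0.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _rng(spec: CommunitySpec, label: str) -> np.random.Generator:
    """Labelled child stream of the master seed (stable across versions)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def generate_metadata(spec: CommunitySpec) -> pd.DataFrame:
    """Per-sample pH (even over the gradient), A/B/C group and covariates."""
    rng = _rng(spec, "metadata")
    lo, hi = spec.ph_range
    ph = np.linspace(lo, hi, spec.n_samples)
    meta = pd.DataFrame(
        {
            "pH": ph,
            "group": [ph_group(p) for p in ph],
            "temperature_C": rng.lognormal(np.log(20.0), 0.12, spec.n_samples),
            "ammonium_mg_kg": rng.lognormal(np.log(10.0), 0.4, spec.n_samples),
        },
        index=pd.Index([f"S{i + 1:02d}" for i in range(spec.n_samples)], name="sample_id"),
    )
    return meta


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------

def _keystone_loading(spec: CommunitySpec, ph: np.ndarray) -> float:
    """Latent pH loading giving the target keystone-pH correlation.

    With latent L = b*x + eps, eps ~ N(0, sd^2), corr(L, x) = rho requires
    b = rho * sd / (sd(x) * sqrt(1 - rho^2)).
    """
    rho = spec.keystone_ph_slope
    sdx = float(np.std(ph))
    sd_eps = max(spec.noise_sd, 1e-6)
    return rho * sd_eps / (sdx * np.sqrt(max(1.0 - rho**2, 1e-9)))


def generate_community(spec: CommunitySpec, meta: pd.DataFrame):
    """Latent-factor community with a planted keystone and cooperation block.

    Latent log-abundance of taxon i in sample s is
    ``baseline_i + loading_i * (pH_s - mean pH) + block term + noise``;
    cooperation-block taxa load on the keystone's own latent signal so that
    their pairwise correlation with the keystone approaches
    ``spec.block_keystone_r``.  Counts are multinomial at
    ``sequencing_depth`` over the softmax of the latent matrix.

    Returns
    -------
    (AbundanceTable, SyntheticTruth)
    """
    rng = _rng(spec, "community")
    n_t, n_s = spec.n_taxa, spec.n_samples
    ph = meta["pH"].to_numpy()
    x = ph - ph.mean()

    taxa = [f"T{i + 1:04d}" for i in range(n_t)]
    keystone = taxa[0]
    block = taxa[1 : 1 + spec.coop_block_size]

    baseline = rng.normal(0.0, spec.baseline_sd, n_t)
    baseline[0] = spec.keystone_baseline
    baseline[1 : 1 + spec.coop_block_size] = spec.block_baseline
    loading = rng.normal(0.0, spec.ph_loading_sd, n_t)

    eps = rng.normal(0.0, spec.noise_sd, (n_t, n_s))
    latent = np.empty((n_t, n_s))

    b_key = _keystone_loading(spec, ph)
    latent[0] = baseline[0] + b_key * x + eps[0]
    key_signal = latent[0] - latent[0].mean()

    # gamma chosen so latent corr(block_i, keystone) ~= block_keystone_r
    sd_key = np.sqrt((b_key * np.std(x)) ** 2 + spec.noise_sd**2)
    r_b = spec.block_keystone_r
    gamma = r_b * spec.noise_sd / (sd_key * np.sqrt(max(1.0 - r_b**2, 1e-9)))

    for i in range(1, n_t):
        if taxa[i] in block:
            latent[i] = baseline[i] + gamma * key_signal + eps[i]
        else:
            latent[i] = baseline[i] + loading[i] * x + eps[i]

    # multinomial counts over softmax per sample
    logits = latent - latent.max(axis=0, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.empty((n_t, n_s), dtype=np.int64)
    for s in range(n_s):
        counts[:, s] = rng.multinomial(spec.sequencing_depth, probs[:, s])

    taxonomy = _make_taxonomy(taxa, keystone, block)
    table = AbundanceTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=meta.index),
        taxonomy,
    )

    rrn_map = _make_rrn_map(spec, taxa, keystone, block, loading, rng)
    truth = SyntheticTruth(
        keystone_id=keystone,
        coop_block_ids=list(block),
        rrn_map=rrn_map,
        planted_shift=spec.planted_shift,
    )
    return table, truth


def _make_taxonomy(taxa, keystone, block) -> pd.DataFrame:
    """Simple nested lineage; the keystone is labelled as a Nitrospira."""
    phyla = ["Proteobacteria", "Acidobacteriota", "Actinobacteriota",
             "Bacteroidota", "Chloroflexota", "Verrucomicrobiota"]
    rows = []
    for i, t in enumerate(taxa):
        if t == keystone:
            rows.append(("Bacteria", "Nitrospirota", "Nitrospiria", "Nitrospirales",
                         "Nitrospiraceae", "Nitrospira", "unclassified"))
        else:
            p = phyla[i % len(phyla)]
            rows.append(("Bacteria", p, f"{p}_c", f"Order_{i % 20:02d}",
                         f"Family_{i // 5:02d}", f"Genus_{i:03d}", "unclassified"))
    return pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"), columns=list(RANKS))


def _make_rrn_map(spec, taxa, keystone, block, loading, rng) -> dict:
    """rrn copies per taxon: acid-favoured (negative pH loading) taxa get few.

    The keystone and its block are single-operon slow growers (the Nitrospira
    trait); other taxa scale with their standardized pH loading
    (``rrn_loading_slope`` copies per loading sd) plus jitter, clipped to
    [1, 15] as in rrndb.
    """
    block = set(block)
    scale = max(spec.ph_loading_sd, 1e-9)
    rrn = {}
    for i, t in enumerate(taxa):
        if t == keystone or t in block:
            rrn[t] = 1
        else:
            val = 3.0 + spec.rrn_loading_slope * loading[i] / scale + rng.normal(0.0, 0.5)
            rrn[t] = int(np.clip(round(val), 1, 15))
    return rrn


def rrn_lookup_from_truth(truth: SyntheticTruth, taxonomy: pd.DataFrame) -> RrnLookup:
    """Genus-level rrndb-style lookup table matching the planted rrn map."""
    rows = []
    for taxon, copies in truth.rrn_map.items():
        rows.append({"name": taxonomy.loc[taxon, "genus"], "rank": "genus",
                     "copies": float(copies)})
    df = pd.DataFrame(rows).drop_duplicates(subset=["name", "rank"])
    return RrnLookup(df)


# ---------------------------------------------------------------------------
# guild-level amoA qPCR table
# ---------------------------------------------------------------------------

def generate_guild_amoa(
    meta: pd.DataFrame,
    spec: CommunitySpec,
    truth: SyntheticTruth | None = None,
    community: AbundanceTable | None = None,
) -> pd.DataFrame:
    """log10 amoA copies/g soil per sample for AOA, AOB and comammox.

    Only the comammox guild trends with pH (slope ``comammox_ph_effect``
    log10 copies per pH unit, anchored at pH 6.5); AOA and AOB are flat.
    When the community table and truth are supplied, the comammox copies also
    inherit the keystone taxon's abundance fluctuations around its pH trend
    (qPCR of the guild marker measures the same DNA the community table
    describes), with correspondingly less independent noise.
    """
    rng = _rng(spec, "guild_amoa")
    base = dict(spec.guild_base_log10)
    out = {}
    ph = meta["pH"].to_numpy()
    for g in GUILDS:
        mu = np.full(len(ph), base[g], dtype=float)
        noise_sd = spec.guild_noise_sd
        if g == "comammox":
            mu = mu + spec.comammox_ph_effect * (ph - GROUP_A_MAX)
            if truth is not None and community is not None:
                rel = community.counts / community.counts.sum(axis=0)
                logk = np.log10(np.maximum(rel.loc[truth.keystone_id].to_numpy(), 1e-12))
                x = ph - ph.mean()
                slope = np.polyfit(x, logk, 1)[0]
                mu = mu + (logk - logk.mean() - slope * x)  # pH-orthogonal residual
                noise_sd = 0.1
        out[g] = mu + rng.normal(0.0, noise_sd, len(ph))
    return pd.DataFrame(out, index=meta.index)


def linear_copies(log10_table: pd.DataFrame) -> pd.DataFrame:
    """Convert a log10 copies/g table to linear copies/g."""
    return 10.0 ** log10_table


# ---------------------------------------------------------------------------
# genome feature table
# ---------------------------------------------------------------------------

@dataclass
class GenomeFeatureTable:
    """Genome x feature booleans plus genome x sample relative abundance."""

    features: pd.DataFrame   # columns mutA, metH, rsmB, stepA, stepB, stepC (bool)
    labels: pd.Series        # genome -> taxon tag ("comammox" / "other")
    abundance: pd.DataFrame  # genome x sample, relative abundance

    CD_GENES = ("mutA", "metH", "rsmB")
    CS_STEPS = ("stepA", "stepB", "stepC")

    def __post_init__(self):
        need = set(self.CD_GENES) | set(self.CS_STEPS)
        if not need.issubset(self.features.columns):
            raise ValueError(f"feature table needs columns {sorted(need)}")
        if self.features[list(need)].isna().any().any():
            raise ValueError("feature booleans must be total (no missing)")
        if (self.abundance.values < 0).any():
            raise ValueError("genome abundances must be >= 0")


def generate_genome_features(
    spec: CommunitySpec,
    truth: SyntheticTruth,
    community: AbundanceTable | None = None,
) -> GenomeFeatureTable:
    """MAG-style feature table: common dependence, rare synthesis capacity.

    The keystone genome (labelled ``comammox``) always carries the full
    synthesis pathway (steps A+B+C); other genomes are full synthesizers with
    probability ``cs_prevalence`` and dependence-gene carriers with
    probability ``cd_prevalence``.  If the community table is supplied, the
    keystone genome's abundance is the keystone taxon's relative abundance.
    """
    rng = _rng(spec, "genomes")
    n_g = spec.n_genomes
    genomes = [f"MAG{i + 1:03d}" for i in range(n_g)]
    key_genome = genomes[0]

    feats = pd.DataFrame(False, index=pd.Index(genomes, name="genome_id"),
                         columns=list(GenomeFeatureTable.CD_GENES)
                         + list(GenomeFeatureTable.CS_STEPS))

    is_cd = rng.random(n_g) < spec.cd_prevalence
    for i, g in enumerate(genomes):
        if is_cd[i]:
            genes = list(GenomeFeatureTable.CD_GENES)
            present = rng.random(3) < 0.5
            if not present.any():
                present[rng.integers(3)] = True
            feats.loc[g, genes] = present

    is_cs = rng.random(n_g) < spec.cs_prevalence
    is_cs[0] = True  # keystone genome always full-CS
    partial = (rng.random(n_g) < spec.partial_bc_prevalence) & ~is_cs
    for i, g in enumerate(genomes):
        if is_cs[i]:
            feats.loc[g, list(GenomeFeatureTable.CS_STEPS)] = True
        elif partial[i]:
            feats.loc[g, ["stepB", "stepC"]] = True

    labels = pd.Series("other", index=feats.index, name="label")
    labels[key_genome] = "comammox"

    # genome x sample relative abundance
    if community is not None:
        samples = community.samples
        rel = community.counts / community.counts.sum(axis=0)
        key_ab = rel.loc[truth.keystone_id].to_numpy()
        n_s = len(samples)
    else:
        n_s = spec.n_samples
        samples = pd.Index([f"S{i + 1:02d}" for i in range(n_s)], name="sample_id")
        ph = np.linspace(*spec.ph_range, n_s)
        b = _keystone_loading(spec, ph)
        lat = spec.keystone_baseline + b * (ph - ph.mean()) + rng.normal(0, spec.noise_sd, n_s)
        key_ab = np.exp(lat)

    # genome-specific abundance level plus modest per-sample jitter (MAG
    # coverages are far more stable across samples than iid noise would be)
    level = rng.lognormal(0.0, spec.genome_level_sd, (n_g, 1))
    raw = level * rng.lognormal(0.0, spec.genome_jitter_sd, (n_g, n_s))
    raw[0] = 0.0
    raw /= raw.sum(axis=0, keepdims=True)
    ab = raw * (1.0 - np.clip(key_ab, 0, 0.9))
    ab[0] = np.clip(key_ab, 0, 0.9)
    abundance = pd.DataFrame(ab, index=feats.index, columns=samples)

    truth.cs_genome_ids = list(feats.index[is_cs])
    truth.cd_genome_ids = list(feats.index[is_cd])
    return GenomeFeatureTable(feats, labels, abundance)


# ---------------------------------------------------------------------------
# SIP density profiles
# ---------------------------------------------------------------------------

def generate_sip_profiles(spec: CommunitySpec, truth: SyntheticTruth) -> pd.DataFrame:
    """Tidy SIP fraction table over 13C/12C treatments, guilds, replicates.

    Copies per fraction follow a discretized Gaussian over buoyant density;
    labelled (13C) profiles of guilds in ``spec.active_guilds`` have their
    peak centre shifted heavier by ``truth.planted_shift``.  Poisson
    measurement noise is applied unless ``spec.sip_noise`` is False.

    Returns columns: treatment, replicate, guild, fraction_index,
    density_g_per_mL, copies.
    """
    rng = _rng(spec, "sip")
    dens = np.linspace(*spec.density_range, spec.n_fractions)
    amp = dict(spec.guild_sip_amplitude)
    rows = []
    for treatment in ("13C", "12C"):
        for guild in GUILDS:
            center = spec.peak_center
            if treatment == "13C" and guild in spec.active_guilds:
                center = center + truth.planted_shift
            shape = np.exp(-0.5 * ((dens - center) / spec.peak_sd) ** 2)
            shape /= shape.sum()
            for rep in range(1, spec.sip_replicates + 1):
                mu = amp[guild] * shape
                copies = rng.poisson(mu).astype(float) if spec.sip_noise else mu
                for k in range(spec.n_fractions):
                    rows.append((treatment, rep, guild, k + 1, dens[k], copies[k]))
    return pd.DataFrame(
        rows,
        columns=["treatment", "replicate", "guild", "fraction_index",
                 "density_g_per_mL", "copies"],
    )


# ---------------------------------------------------------------------------
# one-call bundle + disk writer
# ---------------------------------------------------------------------------

def generate_all(spec: CommunitySpec) -> dict:
    """Generate every artifact for one spec; keys mirror the writers."""
    meta = generate_metadata(spec)
    table, truth = generate_community(spec, meta)
    return {
        "metadata": meta,
        "table": table,
        "truth": truth,
        "guild_amoa_log10": generate_guild_amoa(meta, spec, truth, table),
        "genomes": generate_genome_features(spec, truth, community=table),
        "sip": generate_sip_profiles(spec, truth),
        "rrn_lookup": rrn_lookup_from_truth(truth, table.taxonomy),
    }


def write_all(bundle: dict, outdir) -> None:
    """Write a generated bundle as plain TSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["table"].write_tsv(out / "abundance.tsv")
    bundle["metadata"].to_csv(out / "metadata.tsv", sep="\t")
    bundle["guild_amoa_log10"].to_csv(out / "guild_amoa_log10.tsv", sep="\t")
    bundle["rrn_lookup"].write_tsv(out / "rrn_lookup.tsv")
    g = bundle["genomes"]
    g.features.join(g.labels).to_csv(out / "genome_features.tsv", sep="\t")
    g.abundance.to_csv(out / "genome_abundance.tsv", sep="\t")
    bundle["sip"].to_csv(out / "sip_fractions.tsv", sep="\t", index=False)
    bundle["truth"].to_json(out / "truth.json")
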