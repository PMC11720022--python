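"""Synthetic bulk-expression cohorts with planted ground truth.

The generator emulates the data regime the downstream analysis assumes:
bulk expression is a purity-weighted mixture of fixed tumor and stroma
compartment profiles,

    e_bulk[g, i] = (p_i * e_T[g] + (1 - p_i) * e_S[g]) * exp(eps),
    eps ~ Normal(0, noise_sigma^2),

with multiplicative log-normal noise so values stay positive and the
noise scales with expression.  A ligand-receptor catalog carries planted,
directionally biased pairs: for a pair planted on axis X->Y the ligand's
X-compartment fraction and the receptor's Y-compartment fraction are both
set to ``planted_fraction``, which fixes the pair's true relative
crosstalk score on that axis to ``planted_fraction**2`` (the RC score
factorizes into ligand fraction times receptor fraction).  Survival times
are exponential with a log-linear effect of designated prognostic genes'
standardized bulk expression, censored uniformly.  Evidence sets are
realized exactly from a three-set overlap design so the consensus count
is a deterministic fixture.

Everything is driven by a single integer seed; equal configs produce
bit-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from interactome import io as iio
from interactome.io import ValidationError

__all__ = [
    "AXES",
    "EvidenceOverlapDesign",
    "SimulationConfig",
    "SyntheticBundle",
    "generate_bundle",
    "write_bundle",
]

AXES = ("tt", "ts", "st", "ss")
# axis code -> (ligand compartment, receptor compartment); t = tumor, s = stroma
_AXIS_COMPARTMENTS = {
    "tt": ("t", "t"),
    "ts": ("t", "s"),
    "st": ("s", "t"),
    "ss": ("s", "s"),
}


@dataclass(frozen=True)
class EvidenceOverlapDesign:
    """Exact three-set overlap design.

    ``size_a/b/c`` are total set sizes; ``ab``, ``ac``, ``bc`` are the
    pairwise intersection sizes (each including the triple overlap) and
    ``abc`` the triple intersection size.  The design is valid when every
    exclusive Venn region has nonnegative size.
    """

    size_a: int = 40
    size_b: int = 35
    size_c: int = 30
    ab: int = 6
    ac: int = 5
    bc: int = 4
    abc: int = 2

    def region_sizes(self) -> dict[str, int]:
        """Exclusive Venn region sizes by membership key ('a', 'ab', ...)."""
        regions = {
            "abc": self.abc,
            "ab": self.ab - self.abc,
            "ac": self.ac - self.abc,
            "bc": self.bc - self.abc,
        }
        regions["a"] = self.size_a - self.ab - self.ac + self.abc
        regions["b"] = self.size_b - self.ab - self.bc + self.abc
        regions["c"] = self.size_c - self.ac - self.bc + self.abc
        return regions

    def validate(self) -> None:
        for region, size in self.region_sizes().items():
            if size < 0:
                raise ValidationError(
                    f"inconsistent overlap design: region {region!r} has "
                    f"negative size {size}"
                )

    def consensus_size(self, min_sets: int = 2) -> int:
        """Number of genes in >= min_sets sets under this design."""
        regions = self.region_sizes()
        by_count = {1: ["a", "b", "c"], 2: ["ab", "ac", "bc"], 3: ["abc"]}
        return sum(
            regions[r]
            for count, keys in by_count.items()
            if count >= min_sets
            for r in keys
        )

    def total_genes(self) -> int:
        return sum(self.region_sizes().values())


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults define the study conditions."""

    n_genes: int = 500
    n_samples: int = 100
    n_pairs: int = 150
    n_planted_per_axis: int = 5
    purity_beta_a: float = 5.0
    purity_beta_b: float = 2.0
    purity_clip: tuple[float, float] = (0.05, 0.95)
    noise_sigma: float = 0.1
    planted_fraction: float = 0.9
    n_prognostic: int = 5
    log_hazard_beta: float = -0.7
    baseline_hazard: float = 0.01  # events per month
    censor_max: float = 240.0  # months
    evidence_overlap_design: EvidenceOverlapDesign = field(
        default_factory=EvidenceOverlapDesign
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_pairs) < 1:
            raise ValidationError("n_genes, n_samples, n_pairs must be >= 1")
        if self.n_planted_per_axis < 0:
            raise ValidationError("n_planted_per_axis must be >= 0")
        if 4 * self.n_planted_per_axis > self.n_pairs:
            raise ValidationError(
                f"planted pairs (4 x {self.n_planted_per_axis}) exceed catalog "
                f"size {self.n_pairs}"
            )
        if min(self.purity_beta_a, self.purity_beta_b) <= 0:
            raise ValidationError("purity beta shapes must be positive")
        lo, hi = self.purity_clip
        if not (0 < lo < hi < 1):
            raise ValidationError("purity_clip must satisfy 0 < low < high < 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (0.5 < self.planted_fraction <= 1.0):
            raise ValidationError("planted_fraction must lie in (0.5, 1]")
        if self.baseline_hazard <= 0 or self.censor_max <= 0:
            raise ValidationError("baseline_hazard and censor_max must be positive")
        if self.n_prognostic < 0 or self.n_prognostic > self.n_genes:
            raise ValidationError("n_prognostic out of range")
        if 8 * self.n_planted_per_axis + self.n_prognostic > self.n_genes:
            raise ValidationError(
                "planted-pair and prognostic genes exceed the gene universe"
            )
        if self.evidence_overlap_design.total_genes() > self.n_genes:
            raise ValidationError("overlap design needs more genes than simulated")
        self.evidence_overlap_design.validate()


@dataclass
class SyntheticBundle:
    """A complete synthetic input set plus its ground truth."""

    expression: pd.DataFrame  # genes x samples, nonnegative
    purity: pd.Series  # per sample, in purity_clip bounds
    true_profiles: pd.DataFrame  # gene x (e_tumor, e_stroma), noise-free truth
    catalog: pd.DataFrame  # ligand, receptor, planted_axis
    clinical: pd.DataFrame  # sample x (os_months, os_event, dfs_months, dfs_event)
    evidence: dict[str, set[str]]
    consensus_truth: set[str]  # genes in >= 2 evidence sets, by construction
    prognostic_genes: list[str]
    config: SimulationConfig


def _draw_profiles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    # log-normal compartment means: location 2, scale 1 on the log scale
    e_t = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes)
    e_s = rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes)
    return pd.DataFrame({"e_tumor": e_t, "e_stroma": e_s}, index=pd.Index(genes, name="gene"))


def _plant_pairs(
    config: SimulationConfig,
    profiles: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build the catalog, re-shaping planted genes' compartment split in place."""
    genes = list(profiles.index)
    n_planted = 4 * config.n_planted_per_axis
    if 2 * n_planted > len(genes):
        raise ValidationError("not enough genes for the requested planted pairs")
    rows: list[tuple[str, str, str]] = []
    cursor = 0
    f = config.planted_fraction
    for axis in AXES:
        lig_comp, rec_comp = _AXIS_COMPARTMENTS[axis]
        for _ in range(config.n_planted_per_axis):
            ligand, receptor = genes[cursor], genes[cursor + 1]
            cursor += 2
            for gene, comp in ((ligand, lig_comp), (receptor, rec_comp)):
                total = profiles.loc[gene, "e_tumor"] + profiles.loc[gene, "e_stroma"]
                major, minor = ("e_tumor", "e_stroma") if comp == "t" else ("e_stroma", "e_tumor")
                profiles.loc[gene, major] = f * total
                profiles.loc[gene, minor] = (1 - f) * total
            rows.append((ligand, receptor, axis))
    # background pairs among the remaining genes, unique and non-self
    pool = genes[cursor:]
    seen = {(l, r) for l, r, _ in rows}
    while len(rows) < config.n_pairs:
        ligand, receptor = rng.choice(pool, size=2, replace=False)
        if (ligand, receptor) in seen:
            continue
        seen.add((ligand, receptor))
        rows.append((ligand, receptor, ""))
    return pd.DataFrame(rows, columns=["ligand", "receptor", "planted_axis"])


def _survival_endpoint(
    eta: np.ndarray,
    baseline: float,
    censor_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    hazard = baseline * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, censor_max, size=eta.shape)
    observed = event_time <= censor_time
    time = np.where(observed, event_time, censor_time)
    return time, observed


def _evidence_sets(
    config: SimulationConfig,
    genes: list[str],
    prognostic: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, set[str]], set[str]]:
    """Realize the overlap design exactly.

    Prognostic genes are placed into shared regions first (triple, then
    pairwise) so the synthetic consensus list contains the genes whose
    survival effect is planted; remaining slots are filled from a seeded
    shuffle of the other genes.
    """
    design = config.evidence_overlap_design
    regions = design.region_sizes()
    shared_order = ["abc", "ab", "ac", "bc"]
    placement: dict[str, list[str]] = {key: [] for key in regions}
    prog_iter = iter(prognostic)
    for key in shared_order:
        while len(placement[key]) < regions[key]:
            gene = next(prog_iter, None)
            if gene is None:
                break
            placement[key].append(gene)
        else:
            continue
        break
    used = {g for members in placement.values() for g in members}
    pool = [g for g in genes if g not in used]
    pool = list(rng.permutation(pool))
    for key in ["abc", "ab", "ac", "bc", "a", "b", "c"]:
        while len(placement[key]) < regions[key]:
            placement[key].append(pool.pop())
    sets = {
        "hub_genes": set(),
        "cellchat_signaling": set(),
        "rc_crosstalk": set(),
    }
    letter = {"hub_genes": "a", "cellchat_signaling": "b", "rc_crosstalk": "c"}
    for name, abbrev in letter.items():
        for key, members in placement.items():
            if abbrev in key:
                sets[name].update(members)
    consensus = {
        g
        for key, members in placement.items()
        if len(key) >= 2
        for g in members
    }
    return sets, consensus


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic cohort from ``config`` (deterministic in seed)."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_profiles, rng_catalog, rng_purity, rng_noise, rng_survival, rng_evidence = (
        np.random.default_rng(s) for s in streams
    )

    profiles = _draw_profiles(config, rng_profiles)
    catalog = _plant_pairs(config, profiles, rng_catalog)

    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    lo, hi = config.purity_clip
    purity = np.clip(
        rng_purity.beta(config.purity_beta_a, config.purity_beta_b, config.n_samples),
        lo,
        hi,
    )
    purity_s = pd.Series(purity, index=pd.Index(samples, name="sample"), name="purity")

    mixture = np.outer(profiles["e_tumor"], purity) + np.outer(
        profiles["e_stroma"], 1.0 - purity
    )
    if config.noise_sigma > 0:
        noise = rng_noise.normal(0.0, config.noise_sigma, size=mixture.shape)
        bulk = mixture * np.exp(noise)
    else:
        bulk = mixture
    expression = pd.DataFrame(bulk, index=profiles.index.copy(), columns=samples)

    # prognostic genes: outside the planted-pair block so RC and survival
    # ground truths do not interact
    n_planted_genes = 8 * config.n_planted_per_axis
    prognostic = list(profiles.index[n_planted_genes : n_planted_genes + config.n_prognostic])
    if prognostic:
        z = expression.loc[prognostic].to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        eta = config.log_hazard_beta * z.sum(axis=0)
    else:
        eta = np.zeros(config.n_samples)
    os_time, os_event = _survival_endpoint(
        eta, config.baseline_hazard, config.censor_max, rng_survival
    )
    dfs_time, dfs_event = _survival_endpoint(
        eta, 1.5 * config.baseline_hazard, config.censor_max, rng_survival
    )
    clinical = pd.DataFrame(
        {
            "os_months": os_time,
            "os_event": os_event.astype(int),
            "dfs_months": dfs_time,
            "dfs_event": dfs_event.astype(int),
        },
        index=pd.Index(samples, name="sample"),
    )

    evidence, consensus = _evidence_sets(
        config, list(profiles.index), prognostic, rng_evidence
    )

    return SyntheticBundle(
        expression=expression,
        purity=purity_s,
        true_profiles=profiles,
        catalog=catalog,
        clinical=clinical,
        evidence=evidence,
        consensus_truth=consensus,
        prognostic_genes=prognostic,
        config=config,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Write every bundle artifact to ``outdir``; returns a name->path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "purity": outdir / "purity.tsv",
        "catalog": outdir / "catalog.csv",
        "clinical": outdir / "clinical.tsv",
        "true_profiles": outdir / "true_profiles.tsv",
    }
    iio.write_expression(bundle.expression, paths["expression"])
    iio.write_purity(bundle.purity, paths["purity"])
    iio.write_catalog(bundle.catalog, paths["catalog"])
    iio.write_clinical(bundle.clinical, paths["clinical"])
    iio.write_profiles(bundle.true_profiles, paths["true_profiles"])
    for name, genes in bundle.evidence.items():
        paths[f"evidence_{name}"] = outdir / f"evidence_{name}.txt"
        iio.write_gene_set(genes, paths[f"evidence_{name}"])
    return {name: str(p) for name, p in paths.items()}


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML-friendly)."""
    raw = dict(raw)
    if "evidence_overlap_design" in raw and isinstance(
        raw["evidence_overlap_design"], dict
    ):
        raw["evidence_overlap_design"] = EvidenceOverlapDesign(
            **raw["evidence_overlap_design"]
        )
    if "purity_clip" in raw:
        raw["purity_clip"] = tuple(raw["purity_clip"])
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValidationError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationConfig(**raw)
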