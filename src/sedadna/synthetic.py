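"""Ground-truthed synthetic sediment cores.

Emulates the data a marine sediment-core sedaDNA study produces, with
every quantity known by construction: down-core read libraries whose
eukaryote composition steps from a low diatom fraction to a high one
across a configured age boundary, terminal deamination damage whose
amplitude grows with sample age, undamaged modern contaminant taxa shared
between samples and controls, drill-fluid tracer measurement runs with
blanks and standards, and porewater geochemistry with configured
correlations against the damage driver.

Defaults follow the emulated study design: the diatom fraction steps from
0.08 to 0.50 at 14.5 ka, fragment lengths are lognormal with mode ~56 bp
and a hard 20 bp minimum, and damage grows from a few percent near the
surface to ~33% terminal C→T in the deepest samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .qc import Read, write_fastq
from .taxonomy import (
    ReferenceDB,
    ReferenceSequence,
    TaxonNode,
    TaxonomyTree,
    revcomp,
)
from .tracer import TracerRun, TracerStandard

SAMPLE_KINDS = ("sample", "mudline", "control_air", "control_ebc", "control_drillfluid")
CONTROL_KINDS = ("mudline", "control_air", "control_ebc", "control_drillfluid")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# Configuration blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    site: str
    depth_mbsf: float
    age_ka: float
    kind: str = "sample"
    library_size: int = 5000

    def __post_init__(self):
        if self.kind not in SAMPLE_KINDS:
            raise SimulationError(f"unknown sample kind {self.kind!r}")
        if self.library_size < 0:
            raise SimulationError("library_size must be >= 0")


@dataclass(frozen=True)
class DamageModel:
    """Terminal deamination: C→T at the 5' end, G→A at the 3' end.

    The per-position flip probability decays geometrically from the
    terminus, ``d5 * r**i``; the amplitude d5 ramps linearly with sample
    age from ``d5_surface`` at 0 ka to ``d5_deep`` at ``age_scale`` ka
    (clamped beyond). ``epsilon`` is a uniform background flip channel.
    ``single_stranded`` switches to the single-stranded library signature
    (C→T at both ends).
    """

    d5_surface: float = 0.03
    d5_deep: float = 0.33
    age_scale: float = 400.0
    r: float = 0.5
    epsilon: float = 0.0
    single_stranded: bool = False

    def __post_init__(self):
        for d in (self.d5_surface, self.d5_deep):
            if not 0.0 <= d <= 1.0:
                raise SimulationError("d5 must be in [0, 1]")
        if not 0.0 < self.r < 1.0:
            raise SimulationError("decay ratio r must be in (0, 1)")
        if not 0.0 <= self.epsilon <= 0.05:
            raise SimulationError("epsilon must be in [0, 0.05]")

    def d5_at(self, age_ka: float) -> float:
        frac = min(max(age_ka, 0.0) / self.age_scale, 1.0)
        return self.d5_surface + (self.d5_deep - self.d5_surface) * frac


@dataclass(frozen=True)
class FragmentModel:
    """Lognormal fragment lengths with a hard minimum of 20 bp.

    mode = exp(mu - sigma^2); defaults put the mode at ~56 bp, the length
    scale typical of well-preserved sedaDNA fragments.
    """

    mode: float = 56.0
    sigma: float = 0.35
    min_len: int = 20

    def __post_init__(self):
        if self.mode < self.min_len:
            raise SimulationError("fragment mode must be >= the hard minimum")
        if self.sigma < 0:
            raise SimulationError("sigma must be >= 0")

    @property
    def mu(self) -> float:
        return math.log(self.mode) + self.sigma**2


@dataclass(frozen=True)
class CompositionModel:
    """Eukaryote mixing proportions with a diatom step change.

    The diatom group holds ``diatom_pre`` of the non-contaminant
    community in samples older than ``boundary_age_ka`` and
    ``diatom_post`` in younger ones; the remainder is spread uniformly
    over the other eukaryote taxa. ``contaminant_rate`` of each sample
    library comes from the undamaged contaminant taxa; control and
    mudline libraries contain only contaminant reads.
    """

    diatom_pre: float = 0.08
    diatom_post: float = 0.50
    boundary_age_ka: float = 14.5
    contaminant_rate: float = 0.05

    def __post_init__(self):
        for p in (self.diatom_pre, self.diatom_post, self.contaminant_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("proportions must be in [0, 1]")

    def diatom_fraction(self, age_ka: float) -> float:
        return self.diatom_pre if age_ka > self.boundary_age_ka else self.diatom_post


@dataclass(frozen=True)
class TracerModel:
    """One GC batch: blanks, calibration standards, core measurements.

    ``blanks_zero`` reproduces the regime where every blank reads exactly
    zero (forcing the lowest-standard fallback for the detection limit).
    Injected periphery/centre concentrations are chosen well above
    5x the blank SD so verdicts are separable from noise.
    """

    n_blanks: int = 2
    blank_mean: float = 0.05
    blank_sd: float = 0.02
    blanks_zero: bool = False
    standard_levels: tuple[float, ...] = (0.5, 1.0, 5.0)
    n_standard_reps: int = 2
    standard_sd: float = 0.02
    isomer_fraction: float = 0.88
    periphery_conc: float = 1.0
    centre_conc: float = 0.5
    measurement_sd: float = 0.01

    def __post_init__(self):
        if self.n_blanks < 2:
            raise SimulationError("a run needs at least duplicate blanks")
        if not self.standard_levels:
            raise SimulationError("a run needs at least one standard level")


#: Pearson targets against the damage driver, taken from the emulated
#: study's reported damage-vs-geochemistry correlations.
DEFAULT_GEOCHEM_TARGETS: dict[str, float] = {
    "ammonium": 0.56,
    "alkalinity": 0.52,
    "phosphate": 0.44,
    "sulfate": -0.42,
    "temperature": 0.31,
    "silicon": 0.26,
    "d18O": 0.32,
    "pH": 0.09,
    "salinity": -0.15,
}

DEFAULT_GEOCHEM_MARGINALS: dict[str, tuple[float, float]] = {
    "ammonium": (1.5, 0.6),      # mMol/L
    "alkalinity": (8.0, 3.0),    # mMol/L
    "phosphate": (0.05, 0.02),   # mMol/L
    "sulfate": (20.0, 5.0),      # mMol/L
    "temperature": (5.0, 3.0),   # degC
    "silicon": (400.0, 150.0),   # uM
    "d18O": (4.0, 0.5),          # permil
    "pH": (7.8, 0.2),
    "salinity": (34.5, 0.3),
}


@dataclass(frozen=True)
class GeochemModel:
    """Gaussian-copula covariates with configured correlation targets."""

    targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GEOCHEM_TARGETS)
    )
    marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GEOCHEM_MARGINALS)
    )

    def __post_init__(self):
        for var, rho in self.targets.items():
            if abs(rho) > 1.0:
                raise SimulationError(f"target correlation for {var} outside [-1, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    samples: tuple[SampleSpec, ...] = ()
    composition: CompositionModel = field(default_factory=CompositionModel)
    damage: DamageModel = field(default_factory=DamageModel)
    fragment: FragmentModel = field(default_factory=FragmentModel)
    seq_error: float = 0.001
    tracer: TracerModel = field(default_factory=TracerModel)
    geochem: GeochemModel = field(default_factory=GeochemModel)
    ref_length: int = 400
    read_strand_bias: float = 0.5  # probability a read is emitted forward


# ---------------------------------------------------------------------------
# Default taxonomy and references
# ---------------------------------------------------------------------------


def default_taxonomy() -> tuple[TaxonomyTree, dict[str, list[int]]]:
    """A small marine-eukaryote taxonomy with diatoms, other plankton
    groups, and fungal contaminant lineages.

    Returns the tree and taxon groups: 'diatoms', 'others',
    'contaminants' (species-level ids used as read sources).
    """
    nodes = [
        TaxonNode(1, 1, "root", "root"),
        TaxonNode(2, 1, "domain", "Eukaryota"),
        # Diatoms with genus-level structure
        TaxonNode(10, 2, "phylum", "Bacillariophyta"),
        TaxonNode(11, 10, "genus", "Chaetoceros"),
        TaxonNode(12, 11, "species", "Chaetoceros affinis"),
        TaxonNode(13, 10, "genus", "Fragilariopsis"),
        TaxonNode(14, 13, "species", "Fragilariopsis cylindrus"),
        TaxonNode(15, 10, "genus", "Hemiaulus"),
        TaxonNode(16, 15, "species", "Hemiaulus sinensis"),
        # Other eukaryote plankton / metazoans
        TaxonNode(20, 2, "phylum", "Dinoflagellata"),
        TaxonNode(21, 20, "species", "Dinophyceae sp."),
        TaxonNode(30, 2, "phylum", "Retaria"),
        TaxonNode(31, 30, "species", "Polycystinea sp."),
        TaxonNode(40, 2, "phylum", "Chlorophyta"),
        TaxonNode(41, 40, "species", "Micromonas sp."),
        TaxonNode(50, 2, "phylum", "Chordata"),
        TaxonNode(51, 50, "species", "Salpa sp."),
        TaxonNode(60, 2, "phylum", "Annelida"),
        TaxonNode(61, 60, "species", "Polychaeta sp."),
        # Contaminant fungi (modern, undamaged)
        TaxonNode(70, 2, "phylum", "Ascomycota"),
        TaxonNode(71, 70, "species", "Penicillium sp."),
        TaxonNode(80, 2, "phylum", "Basidiomycota"),
        TaxonNode(81, 80, "species", "Coriolopsis gallica"),
    ]
    tree = TaxonomyTree(nodes)
    groups = {
        "diatoms": [12, 14, 16],
        "others": [21, 31, 41, 51, 61],
        "contaminants": [71, 81],
    }
    return tree, groups


def simulate_references(
    tree: TaxonomyTree,
    taxa: Sequence[int],
    seed: int,
    length: int = 400,
    markers: Sequence[str] = ("SSU", "LSU"),
    k: int = 12,
) -> dict[str, ReferenceDB]:
    """Random marker sequences per taxon, one database per marker.

    The last taxon in ``taxa`` is emitted for the last marker only, so a
    merged database detects strictly more taxa than any single-marker
    database (the rationale for combining marker sets).
    """
    rng = np.random.default_rng(seed)
    dbs = {}
    for mi, marker in enumerate(markers):
        seqs = []
        for taxon in taxa:
            if len(markers) > 1 and taxon == taxa[-1] and mi != len(markers) - 1:
                continue
            seq = "".join(
                np.char.decode(rng.choice(_BASES, size=length).view("S1"), "ascii")
            )
            seqs.append(ReferenceSequence(f"{marker}_t{taxon}", taxon, marker, seq))
        dbs[marker] = ReferenceDB(seqs, tree, k=k)
    return dbs


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_fragment_length(params: FragmentModel, seed) -> int:
    """One lognormal fragment length, floored at the hard minimum."""
    rng = _as_rng(seed)
    raw = rng.lognormal(mean=params.mu, sigma=params.sigma)
    return max(params.min_len, int(round(raw)))


def apply_damage(
    fragment: str,
    d5: float,
    r: float,
    epsilon: float = 0.0,
    seed=None,
    single_stranded: bool = False,
) -> tuple[str, list[tuple[int, str]]]:
    """Apply terminal deamination and background flips to one fragment.

    Each C at 5'-position i flips to T with probability ``d5 * r**i``;
    each G at position j from the 3' end flips to A with the same law
    (C→T at both ends in single-stranded mode). Afterwards every base
    flips to one of the three other bases with probability ``epsilon``.
    Damage flip positions are recorded as ``(position, 'C>T'|'G>A')``;
    background flips are not damage and are not recorded.
    """
    if not 0.0 <= d5 <= 1.0:
        raise ValueError("d5 must be in [0, 1]")
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rng = _as_rng(seed)
    seq = list(fragment)
    L = len(seq)
    positions: list[tuple[int, str]] = []
    for i in range(L):
        if seq[i] == "C" and rng.random() < d5 * r**i:
            seq[i] = "T"
            positions.append((i, "C>T"))
    for j in range(L):
        pos = L - 1 - j
        if single_stranded:
            if seq[pos] == "C" and rng.random() < d5 * r**j:
                seq[pos] = "T"
                positions.append((pos, "C>T"))
        else:
            if seq[pos] == "G" and rng.random() < d5 * r**j:
                seq[pos] = "A"
                positions.append((pos, "G>A"))
    if epsilon > 0:
        for i in range(L):
            if rng.random() < epsilon:
                others = [b for b in "ACGT" if b != seq[i]]
                seq[i] = others[rng.integers(0, 3)]
    positions.sort()
    return "".join(seq), positions


def _apply_seq_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            others = [b for b in "ACGT" if b != out[i]]
            out[i] = others[rng.integers(0, 3)]
    return "".join(out)


def simulate_tracer_run(
    model: TracerModel,
    seed,
    run_id: str = "run1",
    site: str = "SITE",
    scenarios: Mapping[str, str] | None = None,
) -> tuple[TracerRun, dict[str, str]]:
    """One GC measurement batch with known per-sample contamination truth.

    ``scenarios`` maps sample_id → 'clean' | 'periphery' | 'centre'; the
    returned truth dict echoes it (defaults to a three-sample run with
    one of each).
    """
    rng = _as_rng(seed)
    if scenarios is None:
        scenarios = {"S1": "clean", "S2": "periphery", "S3": "centre"}
    if model.blanks_zero:
        blanks = tuple(0.0 for _ in range(model.n_blanks))
    else:
        blanks = tuple(
            max(0.0, rng.normal(model.blank_mean, model.blank_sd))
            for _ in range(model.n_blanks)
        )
    standards = []
    for level in model.standard_levels:
        effective = level * model.isomer_fraction
        reps = tuple(
            max(0.0, rng.normal(effective, model.standard_sd))
            for _ in range(model.n_standard_reps)
        )
        standards.append(TracerStandard(nominal=level, replicates=reps))
    measurements = []
    blank_base = 0.0 if model.blanks_zero else model.blank_mean
    for sample_id, scenario in scenarios.items():
        if scenario == "clean":
            peri, cent = 0.0, 0.0
        elif scenario == "periphery":
            peri, cent = model.periphery_conc, 0.0
        elif scenario == "centre":
            peri, cent = model.periphery_conc, model.centre_conc
        else:
            raise SimulationError(f"unknown tracer scenario {scenario!r}")
        for location, injected in (("periphery", peri), ("centre", cent)):
            # Below the instrument floor the GC reports exactly zero; only
            # genuinely tracer-bearing material carries measurement noise.
            if injected == 0.0:
                value = 0.0
            else:
                value = max(
                    0.0, blank_base + injected + rng.normal(0.0, model.measurement_sd)
                )
            measurements.append((sample_id, location, value))
    run = TracerRun(
        run_id=run_id,
        site=site,
        blanks=blanks,
        standards=tuple(standards),
        measurements=tuple(measurements),
    )
    return run, dict(scenarios)


def simulate_geochem(
    model: GeochemModel, damage_driver: pd.Series, seed
) -> pd.DataFrame:
    """Covariate columns correlated with the damage driver.

    Gaussian copula: each column is ``rho * z + sqrt(1-rho^2) * noise``
    on the standardised scale, mapped to its configured mean/sd.
    |rho| == 1 is honoured as an exact linear copy.
    """
    rng = _as_rng(seed)
    z = damage_driver.to_numpy(dtype=float)
    sd = z.std()
    if sd == 0:
        raise SimulationError("damage driver is constant; correlations undefined")
    z = (z - z.mean()) / sd
    out = {}
    for var, rho in model.targets.items():
        mean, scale = model.marginals.get(var, (0.0, 1.0))
        if abs(rho) == 1.0:
            x = math.copysign(1.0, rho) * z
        else:
            noise = rng.standard_normal(len(z))
            x = rho * z + math.sqrt(1.0 - rho**2) * noise
        out[var] = mean + scale * x
    return pd.DataFrame(out, index=damage_driver.index)


# ---------------------------------------------------------------------------
# Whole-core simulation
# ---------------------------------------------------------------------------


def default_samples(
    site: str = "U1538", reads_per_sample: int = 5000, control_size: int = 200
) -> tuple[SampleSpec, ...]:
    """A 12-sample down-core series straddling the 14.5 ka boundary,
    plus mudline and the three control types."""
    ages = [0.5, 2.0, 5.0, 8.0, 11.0, 13.0, 16.0, 20.0, 34.0, 60.0, 120.0, 392.0]
    depths = [0.1, 0.6, 1.5, 2.4, 3.3, 4.1, 5.0, 6.2, 18.6, 26.6, 41.7, 118.4]
    samples = [
        SampleSpec(f"{site}_S{i:02d}", site, d, a, "sample", reads_per_sample)
        for i, (d, a) in enumerate(zip(depths, ages), start=1)
    ]
    samples.append(SampleSpec(f"{site}_MUDLINE", site, 0.0, 0.0, "mudline", control_size))
    samples.append(SampleSpec(f"{site}_CtrlAir", site, 0.0, 0.0, "control_air", control_size))
    samples.append(SampleSpec(f"{site}_EBC", site, 0.0, 0.0, "control_ebc", control_size))
    samples.append(
        SampleSpec(f"{site}_CtrlPFT", site, 0.0, 0.0, "control_drillfluid", control_size)
    )
    return tuple(samples)


def default_config(seed: int = 0, reads_per_sample: int = 5000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, samples=default_samples(reads_per_sample=reads_per_sample)
    )


@dataclass
class CoreSimulation:
    """Everything one simulated core yields, truth included."""

    config: SimulationConfig
    tree: TaxonomyTree
    groups: dict[str, list[int]]
    dbs: dict[str, ReferenceDB]
    reads: dict[str, list[Read]]
    truth: pd.DataFrame
    sample_truth: pd.DataFrame
    tracer_runs: list[TracerRun]
    tracer_truth: dict[str, str]
    geochem: pd.DataFrame

    def all_reads(self) -> list[Read]:
        out: list[Read] = []
        for sample in self.config.samples:
            out.extend(self.reads[sample.sample_id])
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in self.reads.items():
            write_fastq(reads, outdir / f"{sample_id}.fastq")
        self.truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.sample_truth.to_csv(outdir / "truth_samples.tsv", sep="\t")
        self.geochem.to_csv(outdir / "geochem.tsv", sep="\t")
        rows = []
        for run in self.tracer_runs:
            rows.extend(run.to_rows())
        pd.DataFrame(
            rows,
            columns=["run_id", "site", "kind", "sample_id", "location", "nominal_level", "value"],
        ).to_csv(outdir / "tracer.tsv", sep="\t", index=False)


def _composition(
    config: SimulationConfig, groups: dict[str, list[int]], spec: SampleSpec
) -> tuple[list[int], np.ndarray]:
    comp = config.composition
    diatoms, others, contams = (
        groups["diatoms"],
        groups["others"],
        groups["contaminants"],
    )
    if spec.kind != "sample":
        # Controls and mudline carry only modern contaminant reads; with
        # no contaminants configured they are empty.
        if not contams or comp.contaminant_rate == 0.0:
            return [], np.zeros(0)
        taxa = list(contams)
        probs = np.full(len(contams), 1.0 / len(contams))
        return taxa, probs
    p_diatom = comp.diatom_fraction(spec.age_ka)
    c = comp.contaminant_rate if contams else 0.0
    taxa = list(diatoms) + list(others) + list(contams)
    probs = np.concatenate(
        [
            np.full(len(diatoms), (1 - c) * p_diatom / len(diatoms)),
            np.full(len(others), (1 - c) * (1 - p_diatom) / len(others)),
            np.full(len(contams), c / len(contams)) if contams else np.zeros(0),
        ]
    )
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"composition sums to {total}, not 1")
    return taxa, probs / total


def simulate_core(
    config: SimulationConfig,
    tree: TaxonomyTree | None = None,
    groups: dict[str, list[int]] | None = None,
    dbs: dict[str, ReferenceDB] | None = None,
) -> CoreSimulation:
    """Simulate the full core: reads, truth, tracer runs, geochemistry.

    Deterministic given the config seed. Sample and control libraries
    contain exactly their configured number of reads; control and mudline
    libraries contain only modern contaminant reads.
    """
    if not config.samples:
        raise SimulationError("no samples configured")
    if tree is None or groups is None:
        tree, groups = default_taxonomy()
    if dbs is None:
        source_taxa = groups["diatoms"] + groups["others"] + groups["contaminants"]
        dbs = simulate_references(
            tree, source_taxa, seed=config.seed + 1_000_003, length=config.ref_length
        )

    # Source pool: every (taxon, marker) reference available for a taxon.
    refs_by_taxon: dict[int, list[ReferenceSequence]] = {}
    for db in dbs.values():
        for ref in db.sequences.values():
            refs_by_taxon.setdefault(ref.taxon_id, []).append(ref)

    reads: dict[str, list[Read]] = {}
    truth_rows = []
    sample_rows = []
    for si, spec in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, si])
        taxa, probs = _composition(config, groups, spec)
        d5 = config.damage.d5_at(spec.age_ka) if spec.kind == "sample" else 0.0
        lib: list[Read] = []
        n_reads = spec.library_size if len(taxa) else 0
        for ri in range(n_reads):
            taxon = int(rng.choice(taxa, p=probs))
            is_contaminant = taxon in groups["contaminants"]
            refs = refs_by_taxon[taxon]
            ref = refs[int(rng.integers(0, len(refs)))]
            L = min(
                simulate_fragment_length(config.fragment, rng), len(ref.sequence)
            )
            start = int(rng.integers(0, len(ref.sequence) - L + 1))
            template = ref.sequence[start : start + L]
            strand = "+" if rng.random() < config.read_strand_bias else "-"
            if strand == "-":
                template = revcomp(template)
            if is_contaminant or spec.kind != "sample":
                seq, dpos = template, []
            else:
                seq, dpos = apply_damage(
                    template,
                    d5,
                    config.damage.r,
                    epsilon=config.damage.epsilon,
                    seed=rng,
                    single_stranded=config.damage.single_stranded,
                )
            seq = _apply_seq_error(seq, config.seq_error, rng)
            read_id = f"{spec.sample_id}:{ri}"
            lib.append(Read(read_id, spec.sample_id, seq))
            truth_rows.append(
                (
                    read_id,
                    spec.sample_id,
                    taxon,
                    ref.ref_id,
                    start,
                    strand,
                    is_contaminant,
                    ";".join(f"{p}:{k}" for p, k in dpos),
                    len(dpos),
                    template,
                )
            )
        reads[spec.sample_id] = lib
        if len(taxa):
            diatom_mask = np.isin(np.asarray(taxa), groups["diatoms"])
            diatom_frac = float(probs[diatom_mask].sum())
        else:
            diatom_frac = 0.0
        sample_rows.append(
            (
                spec.sample_id,
                spec.site,
                spec.depth_mbsf,
                spec.age_ka,
                spec.kind,
                d5,
                diatom_frac,
                spec.library_size if len(taxa) else 0,
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "sample_id", "taxon_id", "ref_id", "ref_start",
            "strand", "is_contaminant", "damage_positions", "n_damage", "template",
        ],
    )
    sample_truth = pd.DataFrame(
        sample_rows,
        columns=[
            "sample_id", "site", "depth_mbsf", "age_ka", "kind",
            "true_d5", "true_diatom_fraction", "library_size",
        ],
    ).set_index("sample_id")

    # Tracer: one run per site, real samples only.
    tracer_runs = []
    tracer_truth: dict[str, str] = {}
    sites = sorted({s.site for s in config.samples})
    t_rng = np.random.default_rng([config.seed, 9_999])
    for site in sites:
        site_samples = [
            s.sample_id for s in config.samples if s.site == site and s.kind == "sample"
        ]
        if not site_samples:
            continue
        scen = {}
        for i, sid in enumerate(site_samples):
            if i % 5 == 1:
                scen[sid] = "periphery"
            elif i % 5 == 3:
                scen[sid] = "centre"
            else:
                scen[sid] = "clean"
        run, tt = simulate_tracer_run(
            config.tracer, t_rng, run_id=f"{site}_run1", site=site, scenarios=scen
        )
        tracer_runs.append(run)
        tracer_truth.update(tt)

    core = sample_truth[sample_truth["kind"] == "sample"]
    geochem = simulate_geochem(
        config.geochem, core["true_d5"], np.random.default_rng([config.seed, 77])
    )
    geochem.insert(0, "age_ka", core["age_ka"])
    geochem.insert(0, "depth_mbsf", core["depth_mbsf"])

    return CoreSimulation(
        config=config,
        tree=tree,
        groups=groups,
        dbs=dbs,
        reads=reads,
        truth=truth,
        sample_truth=sample_truth,
        tracer_runs=tracer_runs,
        tracer_truth=tracer_truth,
        geochem=geochem,
    )


def truth_hits(
    sim: CoreSimulation, sample_ids: Iterable[str] | None = None
) -> list[AlignmentHit]:
    """Ungapped alignments of each read against its true source window.

    Uses the simulator's per-read provenance instead of a database
    search: the reference column is the undamaged template, so every
    damage or error flip surfaces as one mismatch at its true position.
    Useful for exercising the damage machinery with alignment search
    noise excluded.
    """
    wanted = set(sample_ids) if sample_ids is not None else None
    lookup = {
        (r.sample_id, r.read_id): r.sequence
        for lib in sim.reads.values()
        for r in lib
    }
    hits = []
    for row in sim.truth.itertuples(index=False):
        if wanted is not None and row.sample_id not in wanted:
            continue
        seq = lookup[(row.sample_id, row.read_id)]
        template = row.template
        mismatches = tuple(
            (i, template[i], seq[i]) for i in range(len(seq)) if seq[i] != template[i]
        )
        matches = len(seq) - len(mismatches)
        hits.append(
            AlignmentHit(
                read_id=row.read_id,
                ref_id=row.ref_id,
                taxon_id=int(row.taxon_id),
                strand=row.strand,
                score=matches - len(mismatches),
                columns=len(seq),
                matches=matches,
                mismatches=mismatches,
                gaps=0,
                read_insertions=(),
                ref_start=int(row.ref_start),
                ref_end=int(row.ref_start) + len(seq),
            )
        )
    return hits
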