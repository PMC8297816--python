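"""Synthetic fasting-refeeding qPCR experiment generator.

Emulates the two-species design used throughout the package: fast-skeletal
muscle sampled at 10 timepoints (four days of fasting, -96 h to 0 h, then
6 h-72 h of refeeding), 6 fish per timepoint, three stable reference genes,
an fbxo32-like fasting marker, and ohnolog triples (two lineage-specific
ohnologs plus the other lineage's singleton) generated under a known
retention mechanism. Ground truth is returned alongside the Ct tables so
every downstream stage (quantification, statistics, correlation,
classification) can be benchmarked for parameter recovery.

Expression archetypes follow the three canonical fast-muscle response
shapes seen in fasting-refeeding studies:

* ``I``   high before fasting, down-regulated during fasting, recovered
          within 24 h of refeeding;
* ``II``  stable during fasting, rapid increase within 24 h of refeeding;
* ``III`` low when fed, induced by fasting, rapidly repressed on refeeding
          (the fbxo32/atrogene shape).

Profiles are piecewise linear in log2 relative-expression space.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ARCHETYPES = ("I", "II", "III")
MECHANISMS = (
    "redundancy",
    "subfunctionalization",
    "neo_gain",
    "neo_loss",
    "canonical_neo",
)
SPECIES = ("A", "B")

#: Hours relative to the start of refeeding: daily sampling during the
#: 4-day fast, then 6 h, 12 h, 1 d, 2 d, 3 d refed.
DEFAULT_TIMEPOINTS_H = (-96, -72, -48, -24, 0, 6, 12, 24, 48, 72)

#: Refeeding responses are complete within 24 h in all three archetypes.
RECOVERY_H = 24.0

DEFAULT_REF_GENES = (("rpl13", 18.0), ("rpl19", 20.0), ("ppiaa", 24.0))


class UnknownArchetypeError(ValueError):
    """Raised for an archetype id outside {I, II, III}."""


class UnknownMechanismError(ValueError):
    """Raised for a retention mechanism outside the supported enum."""


@dataclass(frozen=True)
class FamilySpec:
    """One simulated ohnolog family.

    ``lineage`` names the species carrying the duplicated pair; the
    singleton is placed in the other species. ``amplitude`` is the log2
    fold range of the responsive archetype; ``partner_amplitude`` sizes
    the residual transient kept by the second duplicate under
    subfunctionalization; ``jitter_sd`` is the per-timepoint log2 SD of
    independent profile jitter distinguishing the three family members.
    """

    name: str
    mechanism: str
    archetype: str = "II"
    lineage: str = "A"
    amplitude: float = 3.0
    jitter_sd: float = 0.1
    partner_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise UnknownMechanismError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        if self.archetype not in ARCHETYPES:
            raise UnknownArchetypeError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if self.lineage not in SPECIES:
            raise ValueError(f"lineage must be one of {SPECIES}, got {self.lineage!r}")

    @property
    def lso_a(self) -> str:
        return f"{self.name}a"

    @property
    def lso_b(self) -> str:
        return f"{self.name}b"

    @property
    def singleton(self) -> str:
        return self.name


@dataclass
class SimConfig:
    """Full description of a simulated fasting-refeeding experiment."""

    seed: int
    families: list[FamilySpec] = field(default_factory=list)
    n_replicates: int = 6
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    ref_genes: tuple[tuple[str, float], ...] = DEFAULT_REF_GENES
    ct_noise_sd: float = 0.25
    biological_cv: float = 0.4
    efficiency: float = 2.0
    #: qPCR reactions run in duplicate wells, averaged on the Ct scale.
    technical_duplicates: int = 2
    fbxo32_amplitude: float = math.log2(60.0)

    def validate(self) -> None:
        tps = np.asarray(self.timepoints_h, dtype=float)
        if not np.all(np.diff(tps) > 0):
            raise ValueError("timepoints_h must be strictly increasing")
        if np.count_nonzero(tps == 0) != 1:
            raise ValueError("exactly one timepoint must equal 0 (refeeding start)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.efficiency <= 1:
            raise ValueError("amplification efficiency must be > 1")
        if self.ct_noise_sd < 0 or self.biological_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        names: set[str] = set()
        for fam in self.families:
            for g in (fam.lso_a, fam.lso_b, fam.singleton):
                if g in names:
                    raise ValueError(f"duplicate gene name {g!r} across families")
                names.add(g)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["families"] = [dataclasses.asdict(f) for f in self.families]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["families"] = [FamilySpec(**f) for f in doc.get("families", [])]
        doc["timepoints_h"] = tuple(doc["timepoints_h"])
        doc["ref_genes"] = tuple((n, float(b)) for n, b in doc["ref_genes"])
        return cls(**doc)


@dataclass(frozen=True)
class TruthRecord:
    mechanism: str
    responsiveness: tuple[bool, bool, bool]  # (lso_a, lso_b, singleton)
    archetypes: tuple[str, str, str]


TruthTable = dict  # family name -> TruthRecord


def archetype_profile(
    archetype: str,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    amplitude: float = 3.0,
) -> np.ndarray:
    """Mean log2 relative expression of one archetype over the time grid.

    Piecewise linear: the fasting arm spans [t_min, 0] and the refeeding
    arm completes at +24 h. Baseline (lowest point of the shape) is 0,
    peak is ``amplitude`` log2 units above it.
    """
    if archetype not in ARCHETYPES:
        raise UnknownArchetypeError(
            f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
        )
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    t = np.asarray(timepoints_h, dtype=float)
    if not (np.any(t < 0) and np.any(t > 0)):
        raise ValueError("timepoints must include fasting (<0) and refed (>0) hours")
    t_min = t.min()
    fast_frac = np.clip(-t / -t_min, 0.0, 1.0)  # 1 at t_min -> 0 at 0 h
    refeed_frac = np.clip(t / RECOVERY_H, 0.0, 1.0)  # 0 at 0 h -> 1 at 24 h
    if archetype == "I":
        vals = np.where(t <= 0, fast_frac, refeed_frac)
    elif archetype == "II":
        vals = np.where(t <= 0, 0.0, refeed_frac)
    else:  # III: induced by fasting, repressed by refeeding
        vals = np.where(t <= 0, 1.0 - fast_frac, 1.0 - refeed_frac)
    return amplitude * vals


def _fasting_transient(
    timepoints_h: Sequence[float], amplitude: float, biphasic: bool = False
) -> np.ndarray:
    """Transient confined to the fasting window, flat from -24 h onwards.

    Ramp form: rises through the second and third fasting timepoints
    (0.8 then 1.0 x amplitude) and shuts off before refeeding — a
    mid-fasting response window nearly orthogonal to all three archetypes
    on the default grid. Biphasic form: +amplitude then -amplitude at the
    second/third fasting timepoints — zero-mean, hence exactly
    uncorrelated (noise-free) with any refeeding-responsive archetype.
    """
    t = np.asarray(timepoints_h, dtype=float)
    fasting_idx = np.flatnonzero(t < 0)
    if len(fasting_idx) < 3:
        raise ValueError("need at least 3 fasting timepoints for a transient")
    vals = np.zeros_like(t)
    if biphasic:
        vals[fasting_idx[1]] = amplitude
        vals[fasting_idx[2]] = -amplitude
    else:
        vals[fasting_idx[1]] = 0.8 * amplitude
        vals[fasting_idx[2]] = amplitude
    return vals


def family_truth_profiles(
    mechanism: str,
    base_archetype: str,
    family: FamilySpec | None = None,
    rng: np.random.Generator | None = None,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[bool, bool, bool]]:
    """Noise-free (up to jitter) log2 profiles for one ohnolog triple.

    Returns ``(profile_a, profile_b, profile_s, responsiveness_truth)``
    where the truth triple records whether each gene's ideal profile
    changes between 0 h and the refed timepoints.

    Mechanism semantics:

    * redundancy — all three members share the ancestral archetype;
    * subfunctionalization — copy *a* keeps the full ancestral shape,
      copy *b* only a narrow mid-fasting transient (a complementary
      temporal sub-domain), the singleton is flat;
    * neo_gain — both copies gained the same nutritional response, the
      singleton stayed flat;
    * neo_loss — both copies lost the refeeding response (retaining a
      shared early-fasting transient that keeps them co-expressed), the
      singleton responds;
    * canonical_neo — copy *a* mirrors the singleton, copy *b* is flat
      (textbook single-copy divergence; the study found none of these).
    """
    if mechanism not in MECHANISMS:
        raise UnknownMechanismError(
            f"unknown mechanism {mechanism!r}; expected one of {MECHANISMS}"
        )
    fam = family or FamilySpec("fam", mechanism, base_archetype)
    rng = rng or np.random.default_rng(0)
    t = np.asarray(timepoints_h, dtype=float)
    base = archetype_profile(base_archetype, t, fam.amplitude)
    flat = np.zeros_like(base)

    def jit(profile: np.ndarray) -> np.ndarray:
        return profile + rng.normal(0.0, fam.jitter_sd, size=len(t))

    # Jitter individuates members that share a responsive archetype. Genes the
    # mechanism defines as nutritionally silent (flat, or the fasting-only
    # transients) are exact: jitter inside the refeeding window would be
    # precisely the regulatory response their ground-truth labels deny, and
    # their replicate scatter comes from the noise model anyway.
    if mechanism == "redundancy":
        a, b, s = jit(base), jit(base), jit(base)
        resp = (True, True, True)
    elif mechanism == "subfunctionalization":
        bump = _fasting_transient(t, fam.partner_amplitude)
        a, b, s = base, bump, flat
        resp = (True, False, False)
    elif mechanism == "neo_gain":
        a, b, s = jit(base), jit(base), flat
        resp = (True, True, False)
    elif mechanism == "neo_loss":
        shared = _fasting_transient(t, fam.amplitude, biphasic=True)
        a, b, s = shared, shared.copy(), base
        resp = (False, False, True)
    else:  # canonical_neo
        a, b, s = jit(base), flat, jit(base)
        resp = (True, False, True)
    return a, b, s, resp


def expression_to_ct(
    log2_expr: np.ndarray,
    ref_baseline_ct: float,
    noise_sd: float,
    biological_cv: float,
    n_replicates: int,
    rng: np.random.Generator,
    efficiency: float = 2.0,
    fish_effects: np.ndarray | None = None,
    n_wells: int = 1,
) -> np.ndarray:
    """Invert the Livak transform: log2 expression -> Ct replicate matrix.

    One cycle corresponds to a factor ``efficiency`` of template, so a
    gene expressed ``e`` log2 units above baseline amplifies
    ``e / log2(efficiency)`` cycles earlier. Biological noise is a
    per-fish log2 offset (shared across genes when ``fish_effects`` is
    supplied by the caller, as :func:`simulate_experiment` does);
    technical noise is per well on the Ct scale, with ``n_wells``
    duplicate wells averaged into the reported Ct.

    Returns an ``(n_timepoints, n_replicates)`` array.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must be > 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1 or n_wells < 1:
        raise ValueError("n_replicates and n_wells must be >= 1")
    expr = np.asarray(log2_expr, dtype=float)
    n_t = len(expr)
    if fish_effects is None:
        fish_effects = (
            rng.normal(0.0, biological_cv, size=(n_t, n_replicates))
            if biological_cv > 0
            else np.zeros((n_t, n_replicates))
        )
    fish_effects = np.asarray(fish_effects, dtype=float)
    if fish_effects.shape != (n_t, n_replicates):
        raise ValueError("fish_effects shape must be (n_timepoints, n_replicates)")
    cycles_per_log2 = 1.0 / math.log2(efficiency)
    tech = rng.normal(0.0, noise_sd, size=(n_t, n_replicates, n_wells)).mean(axis=2)
    return ref_baseline_ct - cycles_per_log2 * (expr[:, None] + fish_effects) + tech


def _species_gene_profiles(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict, dict, TruthTable]:
    """Ideal log2 profiles per species, plus the ground-truth table."""
    t = config.timepoints_h
    profiles: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in SPECIES}
    truth: TruthTable = {}
    for sp in SPECIES:
        profiles[sp]["fbxo32"] = archetype_profile("III", t, config.fbxo32_amplitude)
    for fam in config.families:
        a, b, s, resp = family_truth_profiles(
            fam.mechanism, fam.archetype, fam, rng, t
        )
        other = "B" if fam.lineage == "A" else "A"
        profiles[fam.lineage][fam.lso_a] = a
        profiles[fam.lineage][fam.lso_b] = b
        profiles[other][fam.singleton] = s
        truth[fam.name] = TruthRecord(
            mechanism=fam.mechanism,
            responsiveness=resp,
            archetypes=_truth_archetypes(fam),
        )
    return profiles["A"], profiles["B"], truth


def _truth_archetypes(fam: FamilySpec) -> tuple[str, str, str]:
    per = {
        "redundancy": (fam.archetype,) * 3,
        "subfunctionalization": (fam.archetype, "transient", "flat"),
        "neo_gain": (fam.archetype, fam.archetype, "flat"),
        "neo_loss": ("transient", "transient", fam.archetype),
        "canonical_neo": (fam.archetype, "flat", fam.archetype),
    }
    return per[fam.mechanism]


def simulate_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate the full two-species experiment.

    Returns long-format Ct tables (columns ``sample_id, species,
    timepoint_h, replicate, gene, ct``) for species A and B plus the
    ground-truth table. Deterministic given ``config`` (incl. seed).

    The per-fish biological offset is applied to every gene of that fish,
    references included — it models template-loading variation and
    cancels on reference normalization, as in a real plate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles_a, profiles_b, truth = _species_gene_profiles(config, rng)
    t = np.asarray(config.timepoints_h, dtype=float)
    n_t, n_r = len(t), config.n_replicates

    tables = []
    for sp, profiles in (("A", profiles_a), ("B", profiles_b)):
        fish = rng.normal(0.0, config.biological_cv, size=(n_t, n_r))
        rows: dict[str, list] = {
            "sample_id": [],
            "species": [],
            "timepoint_h": [],
            "replicate": [],
            "gene": [],
            "ct": [],
        }
        sample_ids = np.array(
            [[f"{sp}_t{int(tp)}_r{r + 1}" for r in range(n_r)] for tp in t]
        )
        gene_list = [name for name, _ in config.ref_genes] + sorted(profiles)
        baselines = {name: base for name, base in config.ref_genes}
        for gene in sorted(profiles):
            baselines[gene] = rng.uniform(24.0, 32.0)
        for gene in gene_list:
            expr = (
                np.zeros(n_t)
                if gene in dict(config.ref_genes)
                else profiles[gene]
            )
            ct = expression_to_ct(
                expr,
                baselines[gene],
                config.ct_noise_sd,
                config.biological_cv,
                n_r,
                rng,
                efficiency=config.efficiency,
                fish_effects=fish,
                n_wells=config.technical_duplicates,
            )
            rows["sample_id"].extend(sample_ids.ravel())
            rows["species"].extend([sp] * n_t * n_r)
            rows["timepoint_h"].extend(np.repeat(t, n_r))
            rows["replicate"].extend(np.tile(np.arange(1, n_r + 1), n_t))
            rows["gene"].extend([gene] * n_t * n_r)
            rows["ct"].extend(ct.ravel())
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1], truth


def default_scenario(
    n_per_mechanism: int,
    seed: int,
    mechanisms: Sequence[str] = (
        "redundancy",
        "subfunctionalization",
        "neo_gain",
        "neo_loss",
    ),
    **config_kwargs,
) -> SimConfig:
    """Benchmark scenario: ``n_per_mechanism`` families per mechanism.

    Archetypes cycle over the responsive shapes suited to each mechanism
    and lineages alternate between species so both carry duplications.
    Subfunctionalization families use archetype I or III as ancestral
    shape (archetype II is degenerate there: it is flat throughout
    fasting, leaving no fasting-arm sub-domain for the second copy).
    """
    families = []
    arch_cycle = {
        "redundancy": ("I", "II", "III"),
        "subfunctionalization": ("I", "III"),
        "neo_gain": ("II", "I", "III"),
        "neo_loss": ("II", "I"),
        "canonical_neo": ("II", "III"),
    }
    i = 0
    for mech in mechanisms:
        cyc = arch_cycle[mech]
        for k in range(n_per_mechanism):
            families.append(
                FamilySpec(
                    name=f"{mech}_{k:03d}",
                    mechanism=mech,
                    archetype=cyc[k % len(cyc)],
                    lineage=SPECIES[i % 2],
                )
            )
            i += 1
    return SimConfig(seed=seed, families=families, **config_kwargs)


def write_truth_table(truth: TruthTable, path) -> None:
    doc = {
        name: {
            "mechanism": rec.mechanism,
            "responsiveness": list(rec.responsiveness),
            "archetypes": list(rec.archetypes),
        }
        for name, rec in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
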