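"""Synthetic breeding-population generator with known ground truth.

Emulates the development of introgression-line (IL) populations: an elite
recurrent parent is crossed to a donor, the F1 is backcrossed ``b`` times to
the recurrent parent, then advanced ``s`` generations by single-seed-descent
selfing (one offspring per line per generation, so line identity is
preserved).  Multi-environment phenotypes are simulated from planted QTL
effects plus a polygenic term and environment noise, and truncation
selection can be applied for one or two rounds, re-evaluating survivors with
fresh phenotype noise each round.

Meiosis follows the Haldane (no-interference) model.  Gametes are generated
at marker resolution as the Markov chain that model implies: the gamete
starts on a random parental haplotype and switches haplotype between
adjacent markers with the Haldane recombination fraction
``r = (1 - exp(-2d))/2`` for map distance ``d`` Morgans (``r = 1/2`` across
chromosome boundaries).  This is distributionally identical to drawing
Poisson crossover counts with uniform positions and reading the mosaic off
at the marker loci, and it vectorizes over whole populations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    CODE_MISSING,
    MarkerMap,
    Population,
    expected_donor_allele_freq,
)

__all__ = [
    "TRAITS",
    "ENVIRONMENTS",
    "QtlEffect",
    "SelectionSpec",
    "SimConfig",
    "SimTruth",
    "build_marker_map",
    "simulate_gamete",
    "breed_population",
    "simulate_phenotypes",
    "apply_selection",
    "select_lines",
    "generate_dataset",
]

TRAITS = ("HD", "PH", "PN", "FGN", "TGW", "SF", "GY")
ENVIRONMENTS = ("drought", "low_nitrogen", "normal")

# Baseline trait means per environment: typical values for an elite indica
# background under severe reproductive-stage drought, chronic low-N soil and
# well-managed paddy conditions.
BASELINES: dict[str, dict[str, float]] = {
    "drought": {"HD": 85.0, "PH": 75.0, "PN": 7.5, "FGN": 66.0, "TGW": 19.5, "SF": 52.0, "GY": 10.5},
    "low_nitrogen": {"HD": 60.0, "PH": 75.0, "PN": 5.0, "FGN": 107.0, "TGW": 19.0, "SF": 80.0, "GY": 12.7},
    "normal": {"HD": 75.0, "PH": 95.0, "PN": 11.5, "FGN": 164.0, "TGW": 23.5, "SF": 87.5, "GY": 26.0},
}


@dataclass(frozen=True)
class QtlEffect:
    """A planted QTL: additive per-allele effects by environment and founder.

    ``effects[env][founder]`` is the additive effect of one allele copy from
    that founder on ``trait`` in ``env`` (trait units).  Founders absent from
    the mapping contribute 0; sign changes across environments model G x E.
    """

    chrom: int
    pos_bp: int
    trait: str
    effects: dict[str, dict[str, float]]


@dataclass(frozen=True)
class SelectionSpec:
    """Truncation-selection history applied to the derived lines."""

    trait: str = "GY"
    environment: str = "drought"
    proportion: float = 0.3
    rounds: int = 1
    n_final: int | None = None  # exact number kept after the last round

    def __post_init__(self) -> None:
        if not 0 < self.proportion <= 1:
            raise ValueError(f"proportion must be in (0, 1], got {self.proportion}")
        if self.rounds not in (0, 1, 2):
            raise ValueError(f"rounds must be 0, 1 or 2, got {self.rounds}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic IL study.

    Defaults emulate a desk-scale stand-in for a dense SNP map: 12
    chromosomes of 150 cM / 30 Mb carrying 400 evenly spaced markers each,
    one recurrent parent and three donors, a BC1F4 scheme (b=1, s=3), and
    population sizes 63/68/75 reduced to 18/18/21 by two rounds of
    truncation selection on grain yield under drought.
    """

    n_chromosomes: int = 12
    chrom_len_cM: float = 150.0
    chrom_len_bp: int = 30_000_000
    n_markers_per_chrom: int = 400
    recurrent: str = "HHZ"
    donors: tuple[str, ...] = ("Teqing", "CDR22", "OM1723")
    scheme: tuple[int, int] = (1, 3)
    n_lines: tuple[int, ...] = (63, 68, 75)
    qtl: tuple[QtlEffect, ...] = ()
    heritability: dict = field(
        default_factory=lambda: {"drought": 0.5, "low_nitrogen": 0.5, "normal": 0.6}
    )
    selection: SelectionSpec | None = field(
        default_factory=lambda: SelectionSpec(
            trait="GY", environment="drought", proportion=0.3, rounds=2,
            n_final=None,
        )
    )
    n_selected: tuple[int, ...] | None = (18, 18, 21)
    polygenic_cv: float = 0.05
    yield_component_coupling: bool = True
    missing_rate: float = 0.0
    seasons: tuple[str, ...] = ("S1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.donors) == 0:
            raise ValueError("at least one donor is required")
        if len(self.n_lines) != len(self.donors):
            raise ValueError("n_lines must give one size per donor population")
        if any(n < 1 for n in self.n_lines):
            raise ValueError("population sizes must be >= 1")
        for env, h2 in self.heritability.items():
            if not 0 < h2 <= 1:
                raise ValueError(f"heritability[{env!r}] must be in (0, 1], got {h2}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for q in self.qtl:
            if not 1 <= q.chrom <= self.n_chromosomes:
                raise ValueError(f"QTL chromosome {q.chrom} out of range")
            if not 0 <= q.pos_bp <= self.chrom_len_bp:
                raise ValueError(f"QTL position {q.pos_bp} outside chromosome")
            if q.trait not in TRAITS:
                raise ValueError(f"unknown trait {q.trait!r}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced markers on a uniform physical-to-genetic map."""
    rows = []
    n = config.n_markers_per_chrom
    for c in range(1, config.n_chromosomes + 1):
        # midpoints of n equal windows, 1-based bp
        pos = ((np.arange(n) + 0.5) / n * config.chrom_len_bp).astype(int) + 1
        cm = (np.arange(n) + 0.5) / n * config.chrom_len_cM
        for i in range(n):
            rows.append((f"c{c}m{i + 1}", c, int(pos[i]), float(cm[i])))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "cM"]))


def _gametes(h0: np.ndarray, h1: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent, vectorized over parents.

    ``h0``/``h1`` are (n, M) haplotype-origin arrays; ``r`` the per-marker
    recombination fraction to the previous marker (0.5 at position 0 and at
    chromosome starts, so the starting haplotype is uniform per chromosome).
    """
    switches = rng.random(h0.shape) < r
    chooser = np.cumsum(switches, axis=1) & 1
    return np.where(chooser == 1, h1, h0)


def simulate_gamete(
    hap0: np.ndarray, hap1: np.ndarray, markers: MarkerMap, rng: np.random.Generator
) -> np.ndarray:
    """A single gamete from one parent under the Haldane model.

    ``hap0``/``hap1`` are the parent's two haplotype-origin vectors over the
    map's markers.  On a chromosome of genetic length 0 the gamete is an
    unrecombined copy of one random parental haplotype.
    """
    if len(markers) == 0:
        raise ValueError("empty marker map")
    h0 = np.atleast_2d(np.asarray(hap0))
    h1 = np.atleast_2d(np.asarray(hap1))
    return _gametes(h0, h1, markers.recomb_fractions(), rng)[0]


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    Haplotype origins are stored per marker (0 = recurrent, 1 = donor); the
    segment mosaic per chromosome is derived from them, with breakpoints
    placed at inter-marker midpoints.  ``polygenic_effects`` are the fixed
    per-marker allele substitution effects of the infinitesimal background,
    drawn once at breeding time so that the genetic model does not change
    when phenotypes are re-sampled.
    """

    markers: MarkerMap
    hap0: np.ndarray
    hap1: np.ndarray
    donor_id: str
    recurrent_id: str
    qtl: tuple[QtlEffect, ...]
    polygenic_effects: dict[str, np.ndarray]
    selected_indices: list[np.ndarray] = field(default_factory=list)
    selection_differentials: list[float] = field(default_factory=list)

    def subset(self, idx: np.ndarray) -> "SimTruth":
        return SimTruth(
            markers=self.markers,
            hap0=self.hap0[idx],
            hap1=self.hap1[idx],
            donor_id=self.donor_id,
            recurrent_id=self.recurrent_id,
            qtl=self.qtl,
            polygenic_effects=self.polygenic_effects,
            selected_indices=list(self.selected_indices),
            selection_differentials=list(self.selection_differentials),
        )

    def mosaics(self, line: int) -> dict[int, list[list[tuple[int, int, str]]]]:
        """Founder-segment tiling per chromosome for one line.

        Returns ``{chrom: [segments_hap0, segments_hap1]}`` with segments as
        (start_bp, end_bp, founder) covering each chromosome exactly.
        """
        out: dict[int, list[list[tuple[int, int, str]]]] = {}
        chroms = self.markers.chrom
        pos = self.markers.pos_bp
        names = {0: self.recurrent_id, 1: self.donor_id}
        for c in np.unique(chroms):
            sel = chroms == c
            p = pos[sel]
            chrom_end = int(p[-1]) + (int(p[0]) - 1) + 1  # symmetric margin
            haps = []
            for hap in (self.hap0[line, sel], self.hap1[line, sel]):
                segs: list[tuple[int, int, str]] = []
                start = 1
                for i in range(1, len(hap)):
                    if hap[i] != hap[i - 1]:
                        mid = int((p[i - 1] + p[i]) // 2)
                        segs.append((start, mid, names[int(hap[i - 1])]))
                        start = mid + 1
                segs.append((start, chrom_end, names[int(hap[-1])]))
                haps.append(segs)
            out[int(c)] = haps
        return out


def _draw_polygenic(
    markers: MarkerMap,
    rng: np.random.Generator,
    scheme: tuple[int, int] = (1, 3),
) -> dict[str, np.ndarray]:
    """Per-marker allele-substitution effects of the infinitesimal background.

    One vector per trait, shared by every population of a study (the founder
    alleles are the same loci everywhere).  Effects are pre-scaled so the
    polygenic value of a line has unit variance in expectation under the
    scheme's dosage variance; trait-specific magnitude is applied in
    :func:`genetic_values`.
    """
    from .core import expected_genotype_freqs

    var_d = expected_genotype_freqs(*scheme).dosage_var
    scale = 1.0 / np.sqrt(max(len(markers), 1) * max(var_d, 1e-12))
    return {t: rng.standard_normal(len(markers)) * scale for t in TRAITS}


def breed_population(
    config: SimConfig,
    donor_id: str,
    rng: np.random.Generator,
    markers: MarkerMap | None = None,
    population_id: str | None = None,
    polygenic_effects: dict[str, np.ndarray] | None = None,
) -> tuple[Population, SimTruth]:
    """Breed one IL population: F1 -> b backcrosses -> s selfing generations.

    Single-seed descent is used during selfing, so the number of lines is
    constant across generations.  Genotype-class frequencies over many lines
    converge to :func:`ilqtl.core.expected_genotype_freqs` for the scheme.
    """
    if donor_id not in config.donors:
        raise ValueError(f"unknown donor {donor_id!r}")
    pop_idx = config.donors.index(donor_id)
    n = config.n_lines[pop_idx]
    if n < 1:
        raise ValueError("n_lines must be >= 1")
    if markers is None:
        markers = build_marker_map(config)
    m = len(markers)
    r = markers.recomb_fractions()
    b, s = config.scheme

    # F1: recurrent haplotype + donor haplotype, identical for every line.
    h0 = np.zeros((n, m), dtype=np.uint8)
    h1 = np.ones((n, m), dtype=np.uint8)
    for _ in range(b):
        h1 = _gametes(h0, h1, r, rng)
        h0 = np.zeros((n, m), dtype=np.uint8)
    for _ in range(s):
        g0 = _gametes(h0, h1, r, rng)
        g1 = _gametes(h0, h1, r, rng)
        h0, h1 = g0, g1

    genotypes = (h0 + h1).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = CODE_MISSING

    pid = population_id or f"{config.recurrent}x{donor_id}"
    pop = Population(
        population_id=pid,
        recurrent_id=config.recurrent,
        donor_id=donor_id,
        scheme=config.scheme,
        line_ids=[f"{pid}_L{i + 1:04d}" for i in range(n)],
        genotypes=genotypes,
        markers=markers,
    )
    truth = SimTruth(
        markers=markers,
        hap0=h0,
        hap1=h1,
        donor_id=donor_id,
        recurrent_id=config.recurrent,
        qtl=config.qtl,
        polygenic_effects=(
            polygenic_effects
            if polygenic_effects is not None
            else _draw_polygenic(markers, rng)
        ),
    )
    return pop, truth


def _qtl_marker_index(markers: MarkerMap, chrom: int, pos_bp: int) -> int:
    sel = np.flatnonzero(markers.chrom == chrom)
    if len(sel) == 0:
        raise ValueError(f"no markers on chromosome {chrom}")
    return int(sel[np.argmin(np.abs(markers.pos_bp[sel] - pos_bp))])


def genetic_values(population: Population, truth: SimTruth, config: SimConfig, trait: str, environment: str) -> np.ndarray:
    """Deterministic genetic value of each line: planted QTL + polygenic."""
    n = population.n_lines
    dosage = (truth.hap0 + truth.hap1).astype(float)
    g = np.zeros(n)
    for q in config.qtl:
        if q.trait != trait or environment not in q.effects:
            continue
        j = _qtl_marker_index(population.markers, q.chrom, q.pos_bp)
        d = dosage[:, j]
        eff = q.effects[environment]
        e_donor = eff.get(population.donor_id, 0.0)
        e_rec = eff.get(population.recurrent_id, 0.0)
        g += d * e_donor + (2.0 - d) * e_rec
    # infinitesimal background, scaled to the configured coefficient of variation
    u = truth.polygenic_effects[trait]
    centered = dosage - dosage.mean(axis=0)
    gp = (centered @ u) * config.polygenic_cv * BASELINES[environment][trait]
    return g + gp


def simulate_phenotypes(
    population: Population,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    environments: tuple[str, ...] | None = None,
    seasons: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Simulate line x environment phenotype records for all seven traits.

    Each trait is ``baseline + genetic value + noise`` with the noise
    variance set so the realized narrow-sense heritability matches the
    configured value (a small noise floor is used when the genetic variance
    is zero or h2 = 1).  When yield-component coupling is on, the systematic
    part of GY is proportional to PN x FGN x TGW / 1000, rescaled to the
    environment baseline, so that yield correlates with its components.
    """
    environments = environments or ENVIRONMENTS
    seasons = seasons or config.seasons
    rows = []
    for env in environments:
        h2 = config.heritability.get(env, 0.6)
        for season in seasons:
            values: dict[str, np.ndarray] = {}
            for trait in TRAITS:
                base = BASELINES[env][trait]
                g = genetic_values(population, truth, config, trait, env)
                if trait == "GY" and config.yield_component_coupling:
                    prod = values["PN"] * values["FGN"] * values["TGW"] / 1000.0
                    mean_prod = prod.mean()
                    systematic = prod * (base / mean_prod if mean_prod > 0 else 0.0) + g
                else:
                    systematic = base + g
                var_g = systematic.var()
                floor = (0.02 * base) ** 2
                if var_g <= floor or h2 >= 1.0:
                    var_e = floor
                else:
                    var_e = var_g * (1.0 - h2) / h2
                y = systematic + rng.normal(0.0, np.sqrt(var_e), population.n_lines)
                if trait in ("PN", "FGN", "TGW", "GY"):
                    y = np.maximum(y, 0.0)
                elif trait == "SF":
                    y = np.clip(y, 0.0, 100.0)
                values[trait] = y
            for i, lid in enumerate(population.line_ids):
                rows.append(
                    {"line_id": lid, "environment": env, "season": season}
                    | {t: float(values[t][i]) for t in TRAITS}
                )
    return pd.DataFrame(rows)


def apply_selection(
    population: Population,
    phenotypes: pd.DataFrame,
    trait: str,
    environment: str,
    proportion: float = 1.0,
    n_keep: int | None = None,
) -> tuple[Population, np.ndarray]:
    """One round of truncation selection: keep the top fraction by phenotype.

    Returns the selected sub-population and the retained line indices
    (relative to the input population).  Phenotypes from multiple seasons
    are averaged per line before ranking.
    """
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    sub = phenotypes[phenotypes["environment"] == environment]
    if sub.empty:
        raise ValueError(f"no phenotypes for environment {environment!r}")
    means = sub.groupby("line_id")[trait].mean()
    try:
        y = means.loc[population.line_ids].to_numpy()
    except KeyError as exc:
        raise ValueError(f"phenotypes missing for line {exc}") from exc
    k = n_keep if n_keep is not None else int(np.ceil(proportion * population.n_lines))
    if k < 1:
        raise ValueError("selection would empty the population")
    if k >= population.n_lines:
        return population, np.arange(population.n_lines)
    order = np.argsort(-y, kind="mergesort")
    idx = np.sort(order[:k])
    selected = Population(
        population_id=population.population_id,
        recurrent_id=population.recurrent_id,
        donor_id=population.donor_id,
        scheme=population.scheme,
        line_ids=[population.line_ids[i] for i in idx],
        genotypes=population.genotypes[idx],
        markers=population.markers,
    )
    return selected, idx


def select_lines(
    population: Population,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    n_final: int | None = None,
) -> tuple[Population, SimTruth]:
    """Run the configured selection history, re-phenotyping between rounds.

    Each round simulates fresh phenotypes for the surviving lines (progeny
    re-testing) and truncates.  If ``n_final`` is given the last round keeps
    exactly that many lines; earlier rounds keep a geometric interpolation
    between the initial and final sizes.
    """
    spec = config.selection
    if spec is None or spec.rounds == 0:
        return population, truth
    n0 = population.n_lines
    target = n_final if n_final is not None else spec.n_final
    for rnd in range(spec.rounds):
        ph = simulate_phenotypes(
            population, truth, config, rng, environments=(spec.environment,)
        )
        if target is not None:
            frac = (target / n0) ** ((rnd + 1) / spec.rounds)
            keep = max(target, int(round(n0 * frac)))
            pop2, idx = apply_selection(
                population, ph, spec.trait, spec.environment, n_keep=keep
            )
        else:
            pop2, idx = apply_selection(
                population, ph, spec.trait, spec.environment, proportion=spec.proportion
            )
        sub = ph[ph["environment"] == spec.environment]
        means = sub.groupby("line_id")[spec.trait].mean()
        before = float(means.loc[population.line_ids].mean())
        after = float(means.loc[pop2.line_ids].mean())
        truth = truth.subset(idx)
        truth.selected_indices.append(idx)
        truth.selection_differentials.append(after - before)
        population = pop2
    return population, truth


def generate_dataset(config: SimConfig, out_dir) -> dict:
    """Generate the full study bundle and write it to ``out_dir``.

    One population per donor is bred, phenotyped in all environments, and
    put through the configured selection history.  Writes the marker map,
    per-population genotype matrices (before and after selection),
    phenotypes of the selected lines, a plain-text truth summary and a
    manifest recording the seed and config hash.  Returns the bundle
    in-memory as a dict.
    """
    from pathlib import Path

    from . import io as ilio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    markers = build_marker_map(config)
    ilio.write_marker_map(markers, out / "map.tsv")
    # one set of background allele effects for the whole study
    polygenic = _draw_polygenic(markers, rng, scheme=config.scheme)

    bundle: dict = {"markers": markers, "populations": [], "truths": [], "phenotypes": None}
    pheno_frames = []
    truth_summary: dict = {"qtl": [], "populations": {}}
    for q in config.qtl:
        truth_summary["qtl"].append(
            {"chrom": q.chrom, "pos_bp": q.pos_bp, "trait": q.trait, "effects": q.effects}
        )
    for i, donor in enumerate(config.donors):
        pop, truth = breed_population(
            config, donor, rng, markers=markers, polygenic_effects=polygenic
        )
        ilio.write_genotypes(pop, out / f"{pop.population_id}_genotypes_unselected.tsv")
        n_final = config.n_selected[i] if config.n_selected else None
        sel_pop, sel_truth = select_lines(pop, truth, config, rng, n_final=n_final)
        ilio.write_genotypes(sel_pop, out / f"{sel_pop.population_id}_genotypes.tsv")
        ph = simulate_phenotypes(sel_pop, sel_truth, config, rng)
        pheno_frames.append(ph)
        bundle["populations"].append(sel_pop)
        bundle["truths"].append(sel_truth)
        truth_summary["populations"][pop.population_id] = {
            "donor": donor,
            "n_initial": pop.n_lines,
            "n_selected": sel_pop.n_lines,
            "selected_line_ids": sel_pop.line_ids,
            "selection_differentials": sel_truth.selection_differentials,
        }
    phenotypes = pd.concat(pheno_frames, ignore_index=True)
    bundle["phenotypes"] = phenotypes
    ilio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    (out / "truth.json").write_text(json.dumps(truth_summary, indent=1, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "scheme": list(config.scheme),
        "recurrent": config.recurrent,
        "donors": list(config.donors),
        "n_lines": list(config.n_lines),
        "missing_imputation": "expected dosage (2-2p, 2p) with p=(1/2)^(b+1)",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
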