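"""Domain types and closed-form genotype-frequency / indicator-coding math.

Genotype coding convention used throughout the package: introgression lines
in a recurrent-parent background are scored at each marker as

* ``A`` — homozygous for the recurrent-parent allele,
* ``H`` — heterozygous,
* ``B`` — homozygous for the donor allele,
* ``NA`` — missing.

Internally genotypes are stored as the *donor-allele dosage*: ``int8``
values 0 (A), 1 (H), 2 (B) with -1 for missing.  File I/O (see
:mod:`ilqtl.io`) translates between the letter codes and the dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "CODE_A",
    "CODE_H",
    "CODE_B",
    "CODE_MISSING",
    "GENOTYPE_CODES",
    "MendelianExpectation",
    "MarkerMap",
    "Population",
    "QTLRecord",
    "expected_genotype_freqs",
    "expected_donor_allele_freq",
    "interval_genotype",
    "encode_founder_indicator",
    "founder_indicators",
]

# Donor-allele dosage codes.
CODE_A: int = 0
CODE_H: int = 1
CODE_B: int = 2
CODE_MISSING: int = -1

#: letter <-> dosage translation used by the I/O layer
GENOTYPE_CODES = {"A": CODE_A, "H": CODE_H, "B": CODE_B, "NA": CODE_MISSING}
CODE_LETTERS = {v: k for k, v in GENOTYPE_CODES.items()}


@dataclass(frozen=True)
class MendelianExpectation:
    """Expected genotype-class probabilities for a BC_bF_t line.

    Probabilities are exact rationals; ``pi_A + pi_H + pi_B == 1`` always
    holds by construction.
    """

    pi_A: Fraction
    pi_H: Fraction
    pi_B: Fraction

    def __post_init__(self) -> None:
        total = self.pi_A + self.pi_H + self.pi_B
        if total != 1:
            raise ValueError(f"class probabilities must sum to 1, got {total}")
        for p in (self.pi_A, self.pi_H, self.pi_B):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")

    def as_floats(self) -> np.ndarray:
        return np.array([float(self.pi_A), float(self.pi_H), float(self.pi_B)])

    @property
    def donor_allele_freq(self) -> Fraction:
        return self.pi_H / 2 + self.pi_B

    @property
    def dosage_mean(self) -> float:
        """Expected donor-allele dosage per line (0..2 scale)."""
        return float(2 * self.donor_allele_freq)

    @property
    def dosage_var(self) -> float:
        """Variance of the donor-allele dosage of one line under the null."""
        m = self.dosage_mean
        return float(self.pi_H) + 4.0 * float(self.pi_B) - m * m


def _check_scheme(b: int, s: int) -> None:
    for name, v in (("b", b), ("s", s)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise TypeError(f"{name} must be an integer, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def expected_genotype_freqs(b: int, s: int) -> MendelianExpectation:
    """Expected A:H:B frequencies after ``b`` backcrosses and ``s`` selfings.

    Starting from the F1, each backcross to the recurrent parent halves the
    donor-allele frequency and keeps every donor allele heterozygous; each
    selfing generation halves the heterozygote class, splitting the lost
    heterozygosity equally between the two homozygote classes.  For one
    backcross and three selfings (a BC1F4 line) this gives the familiar
    23/32 : 2/32 : 7/32 ratio.

    Returns exact :class:`fractions.Fraction` probabilities.
    """
    _check_scheme(b, s)
    half = Fraction(1, 2)
    pi_H = half ** (b + s)
    pi_B = half**b * (1 - half**s) / 2
    pi_A = 1 - pi_H - pi_B
    return MendelianExpectation(pi_A=pi_A, pi_H=pi_H, pi_B=pi_B)


def expected_donor_allele_freq(b: int, s: int) -> Fraction:
    """Expected donor-allele frequency, (1/2)^(b+1) for any number of selfings.

    Selfing conserves allele frequency in expectation; only backcrossing to
    the recurrent parent dilutes the donor genome.
    """
    _check_scheme(b, s)
    return expected_genotype_freqs(b, s).donor_allele_freq


def interval_genotype(left: int, right: int) -> int:
    """QTL genotype from two flanking-marker calls.

    The genotype of the interval delimited by two flanking markers stands in
    for the QTL genotype: both calls must agree and be non-missing, otherwise
    the line is treated as recombinant/unscorable and ``CODE_MISSING`` is
    returned.  Symmetric in its arguments.
    """
    if left == right and left != CODE_MISSING:
        return int(left)
    return CODE_MISSING


def encode_founder_indicator(
    call: int,
    donor_index: int,
    n_founders: int = 4,
    scheme: tuple[int, int] | None = None,
    other_index: int = 0,
) -> np.ndarray:
    """Founder allele-inheritance indicator row Z_jk for one line at one locus.

    Founder slot 0 is the recurrent parent; ``donor_index`` identifies the
    founder supplying the ``B`` allele.  A homozygous recurrent call puts
    both allele counts in slot 0 (e.g. ``[2, 0, 0, 0]``), a donor homozygote
    puts both in the donor slot, and a heterozygote one in the donor slot
    and one in ``other_index`` (the recurrent parent by default, but any
    founder in a multi-donor cross: a heterozygote carrying the second and
    third founders' alleles codes as ``[0, 1, 1, 0]``).  Rows always sum
    to 2.

    Missing calls are filled with the scheme's expected dosage vector
    (recurrent slot ``2 - 2 p``, donor slot ``2 p`` with
    ``p = (1/2)^(b+1)``), which keeps the row-sum invariant and is unbiased
    under the Mendelian null; ``scheme`` must then be supplied.
    """
    if not 1 <= donor_index < n_founders:
        raise ValueError(
            f"donor_index must be in [1, {n_founders - 1}], got {donor_index}"
        )
    if not 0 <= other_index < n_founders or other_index == donor_index:
        raise ValueError(f"other_index must name a different founder slot")
    row = np.zeros(n_founders, dtype=float)
    if call == CODE_A:
        row[0] = 2.0
    elif call == CODE_B:
        row[donor_index] = 2.0
    elif call == CODE_H:
        row[other_index] = 1.0
        row[donor_index] = 1.0
    elif call == CODE_MISSING:
        if scheme is None:
            raise ValueError("scheme=(b, s) required to impute a missing call")
        p = float(expected_donor_allele_freq(*scheme))
        row[0] = 2.0 - 2.0 * p
        row[donor_index] = 2.0 * p
    else:
        raise ValueError(f"unknown genotype code {call!r}")
    return row


@dataclass
class MarkerMap:
    """Marker positions on physical (bp) and genetic (cM) coordinates.

    Wraps a DataFrame with columns ``marker_id, chrom, pos_bp, cM`` plus the
    derived 1-based 100-kb bin index.  Markers are kept sorted by
    (chromosome, bp position); marker ids must be unique.  Positions are
    1-based in files and in this table; arrays indexing into the map are
    0-based.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "pos_bp", "cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        t = self.table.copy()
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id {dup!r}")
        if (t["pos_bp"] < 0).any() or (t["cM"] < 0).any():
            raise ValueError("positions must be non-negative")
        t = t.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
        t["bin_100kb"] = t["pos_bp"] // 100_000 + 1
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def bin_100kb(self) -> np.ndarray:
        return self.table["bin_100kb"].to_numpy()

    @property
    def cM(self) -> np.ndarray:
        return self.table["cM"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        idx = self.table.index[self.table["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def recomb_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between consecutive markers.

        Entry ``i`` is the fraction between markers ``i-1`` and ``i``; entry 0
        and every chromosome boundary are 0.5 (free recombination).
        """
        r = np.empty(len(self), dtype=float)
        if len(self) == 0:
            return r
        d_morgan = np.diff(self.cM) / 100.0
        r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        r[0] = 0.5
        new_chrom = np.flatnonzero(np.diff(self.chrom) != 0) + 1
        r[new_chrom] = 0.5
        return r


@dataclass
class Population:
    """One introgression-line population from a single recurrent x donor cross.

    ``genotypes`` holds the donor-allele dosage matrix (lines x markers,
    int8, -1 missing); ``scheme`` is the (backcross, selfing) generation count
    of the breeding design.
    """

    population_id: str
    recurrent_id: str
    donor_id: str
    scheme: tuple[int, int]
    line_ids: list[str]
    genotypes: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        _check_scheme(*self.scheme)
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError(
                f"genotype matrix {g.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.markers)} markers"
            )
        bad = ~np.isin(g, [CODE_A, CODE_H, CODE_B, CODE_MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {g[i, j]} at line {self.line_ids[i]!r}, "
                f"marker {self.markers.marker_ids[j]!r}"
            )
        self.genotypes = g

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def expectation(self) -> MendelianExpectation:
        return expected_genotype_freqs(*self.scheme)


def founder_indicators(
    populations: list[Population],
    founder_order: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack per-locus founder-indicator matrices for a combined population.

    Founder origin is coded from population membership: every line of a
    population draws its two alleles from the shared recurrent parent and
    that population's donor.  Missing calls are imputed with the expected
    dosage for the population's breeding scheme.

    Returns ``(Z, founders, line_ids)`` where ``Z`` has shape
    ``(n_markers, n_lines, n_founders)``, rows summing to 2.
    """
    if not populations:
        raise ValueError("at least one population required")
    recurrent = populations[0].recurrent_id
    if any(p.recurrent_id != recurrent for p in populations):
        raise ValueError("all populations must share the recurrent parent")
    if founder_order is None:
        founders = [recurrent] + [p.donor_id for p in populations]
    else:
        founders = list(founder_order)
        if founders[0] != recurrent:
            raise ValueError("founder_order[0] must be the recurrent parent")
    n_f = len(founders)
    m = len(populations[0].markers)
    ids = populations[0].markers.marker_ids
    for p in populations[1:]:
        if p.markers.marker_ids != ids:
            raise ValueError("populations must share a consensus marker map")

    blocks = []
    line_ids: list[str] = []
    for pop in populations:
        donor_idx = founders.index(pop.donor_id)
        g = pop.genotypes.astype(float)  # dosage of donor allele
        p_donor = float(expected_donor_allele_freq(*pop.scheme))
        g[pop.genotypes == CODE_MISSING] = 2.0 * p_donor
        z = np.zeros((m, pop.n_lines, n_f), dtype=float)
        z[:, :, 0] = 2.0 - g.T
        z[:, :, donor_idx] = g.T
        blocks.append(z)
        line_ids.extend(pop.line_ids)
    Z = np.concatenate(blocks, axis=1)
    return Z, founders, line_ids


@dataclass
class QTLRecord:
    """A called QTL: a (possibly merged) run of significant markers."""

    name: str
    trait: str
    chrom: int
    bin_start: int
    bin_end: int
    pos_start_bp: int
    pos_end_bp: int
    peak_marker: str
    statistic: float
    p_value: float
    favorable_source: list[str] = field(default_factory=list)
    effects: dict[str, float] = field(default_factory=dict)
    pve: float | None = None
    extra: dict = field(default_factory=dict)

    def covers(self, chrom: int, pos_bp: int) -> bool:
        """Whether a physical position falls inside this QTL's bin interval."""
        if chrom != self.chrom:
            return False
        b = pos_bp // 100_000 + 1
        return self.bin_start <= b <= self.bin_end
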