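"""End-to-end evaluation studies: worked examples, calibration, power.

Every function here recomputes its quantities from scratch by running the
package — breeding synthetic populations, scanning, selecting — or by
re-deriving printed worked-example arithmetic from its stated inputs.  The
studies are shared between the test suite and ``scripts/acceptance.py`` so
that both always measure the same study conditions.

Problem sizes (the package's own desk-scale choices, see docs/methods.md):
a 12-chromosome genome of 150 cM / 30 Mb per chromosome; 100 markers per
chromosome for power studies (300-kb spacing), 42 for the association
calibration null (504 markers), and 1,000 single-marker chromosomes for the
segregation-distortion calibration null (exactly independent markers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import association, msd, pyramiding, simulate, traits
from .core import expected_genotype_freqs, founder_indicators

__all__ = [
    "mendelian_worked_example",
    "validation_worked_examples",
    "stress_index_worked_examples",
    "msd_null_calibration",
    "msd_power_study",
    "association_calibration_study",
    "association_power_study",
    "oracle_checks",
    "welch_null_rejection",
    "background_recovery_study",
]


# --------------------------------------------------------------------------
# worked examples (exact arithmetic on published group summaries)

def mendelian_worked_example() -> dict:
    """Genotype-class expectation of a BC1F4 line (1 backcross, 3 selfings)."""
    e = expected_genotype_freqs(1, 3)
    return {
        "pi_A": float(e.pi_A),
        "pi_H": float(e.pi_H),
        "pi_B": float(e.pi_B),
        "pi_A_x32": float(e.pi_A * 32),
        "pi_H_x32": float(e.pi_H * 32),
        "pi_B_x32": float(e.pi_B * 32),
        "donor_allele_freq": float(e.donor_allele_freq),
    }


#: published validation-table group means for the four pyramiding targets:
#: (trait, recurrent-homozygote mean, donor-homozygote mean)
VALIDATION_GROUP_MEANS = {
    "qDT3.9": ("GY", 9.9, 15.1),
    "qDT6.3": ("GY", 10.3, 14.5),
    "qGY1": ("GY", 11.2, 15.6),
    "qSF8": ("SF", 76.3, 84.0),
}


def validation_worked_examples() -> dict:
    """AA-BB differences and donor-class relative gains from group means."""
    out = {}
    for qtl, (trait, mean_aa, mean_bb) in VALIDATION_GROUP_MEANS.items():
        key = qtl.replace(".", "_")
        out[f"{key}_{trait}_diff_AA_minus_BB"] = round(mean_aa - mean_bb, 1)
        out[f"{key}_{trait}_pct_gain_BB_vs_AA"] = pyramiding.percent_change(
            mean_aa, mean_bb
        )
    return out


def stress_index_worked_examples() -> dict:
    """Stress/control GY ratios and reductions of the pyramiding parents.

    Inputs are the published line means: M79 GY 16.8 (drought), 17.5 (LN),
    26.1 (normal); M387 15.6 / 17.1 / 25.7; recurrent check 12.7 (LN),
    26.3 (normal) and 11.2 g under drought after a 13.4 g reduction.
    """
    si = traits.stress_index
    return {
        "M79_GY_drought_over_normal": round(si(16.8, 26.1), 2),
        "M79_GY_LN_over_normal": round(si(17.5, 26.1), 2),
        "M387_GY_drought_over_normal": round(si(15.6, 25.7), 2),
        "HHZ_GY_LN_over_normal": round(si(12.7, 26.3), 2),
        "HHZ_GY_drought_pct_reduction": round(
            traits.percent_reduction(11.2 + 13.4, absolute_reduction=13.4), 1
        ),
    }


# --------------------------------------------------------------------------
# segregation-distortion scan: calibration and power

def _msd_null_config(seed: int) -> simulate.SimConfig:
    # 1,000 single-marker chromosomes: markers exactly independent
    return simulate.SimConfig(
        n_chromosomes=1000,
        chrom_len_cM=0.0,
        chrom_len_bp=100_000,
        n_markers_per_chrom=1,
        n_lines=(20, 20, 20),
        selection=None,
        n_selected=None,
        seed=seed,
    )


def msd_null_calibration(
    seed: int, n_replicates: int = 200
) -> dict:
    """Type-I behavior of the joint MSD scan with no selection.

    Per replicate, three unselected populations of 20 lines are bred at
    1,000 unlinked markers and scanned jointly.  Reports the pooled fraction
    of markers with p < 0.001 (the binomial 99% CI around 0.001 at this
    problem size is [0.00082, 0.00118]) and the fraction of replicates whose
    p-values pass a Kolmogorov-Smirnov uniformity test at the 1% level.
    """
    cfg = _msd_null_config(seed)
    markers = simulate.build_marker_map(cfg)
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    ks_pass = 0
    for _ in range(n_replicates):
        pops = [
            simulate.breed_population(cfg, d, rng, markers=markers)[0]
            for d in cfg.donors
        ]
        pv = msd.msd_joint_scan(pops)["p_value"].to_numpy()
        hits += int((pv < 0.001).sum())
        total += pv.size
        ks_pass += stats.kstest(pv, "uniform").pvalue > 0.01
    return {
        "fraction_p_below_1e3": hits / total,
        "ks_uniformity_pass_rate": ks_pass / n_replicates,
        "n_markers_total": total,
    }


#: planted drought QTL for the selection/power studies: equal favorable
#: donor effects, magnitude giving PVE ~ 20% of drought GY variance
#: (closed form: a^2 var_d h2 / (a^2 var_d + var_poly) * ... solved below)
_MSD_QTL_CHROM = 3
_MSD_QTL_POS = 15_150_001  # at a genotyped marker of the 100-marker map


def _msd_effect_size(pve: float = 0.20, h2: float = 0.5) -> float:
    var_d = expected_genotype_freqs(1, 3).dosage_var
    base = simulate.BASELINES["drought"]["GY"]
    var_poly = (0.05 * base) ** 2
    # pve = h2 * a^2 var_d / (a^2 var_d + var_poly)
    return float(np.sqrt(pve * var_poly / (var_d * (h2 - pve))))


def _msd_power_config(seed: int) -> simulate.SimConfig:
    a = _msd_effect_size()
    qtl = simulate.QtlEffect(
        chrom=_MSD_QTL_CHROM,
        pos_bp=_MSD_QTL_POS,
        trait="GY",
        effects={"drought": {"Teqing": a, "CDR22": a, "OM1723": a}},
    )
    return simulate.SimConfig(
        n_chromosomes=12,
        n_markers_per_chrom=100,
        n_lines=(450, 450, 525),
        n_selected=(18, 18, 21),
        qtl=(qtl,),
        selection=simulate.SelectionSpec("GY", "drought", proportion=0.2, rounds=2),
        heritability={"drought": 0.5, "low_nitrogen": 0.5, "normal": 0.6},
        yield_component_coupling=False,
        seed=seed,
    )


def msd_power_study(seed: int, n_replicates: int = 100) -> dict:
    """Recovery of a planted drought QTL after two rounds of selection.

    Each replicate breeds three populations (450/450/525 lines), applies two
    rounds of truncation selection on grain yield under drought down to
    18/18/21 lines, scans the survivors jointly, and asks whether a called
    QTL interval covers the planted position.
    """
    cfg = _msd_power_config(seed)
    markers = simulate.build_marker_map(cfg)
    rng = np.random.default_rng(seed)
    covered = 0
    donor_excess = 0
    for _ in range(n_replicates):
        poly = simulate._draw_polygenic(markers, rng, scheme=cfg.scheme)
        pops = []
        for i, d in enumerate(cfg.donors):
            pop, truth = simulate.breed_population(
                cfg, d, rng, markers=markers, polygenic_effects=poly
            )
            sel, _ = simulate.select_lines(
                pop, truth, cfg, rng, n_final=cfg.n_selected[i]
            )
            pops.append(sel)
        scan = msd.msd_joint_scan(pops)
        calls = msd.call_msd_qtl(scan, alpha=1e-3, merge_window_bins=5)
        covered += any(q.covers(_MSD_QTL_CHROM, _MSD_QTL_POS) for q in calls)
        j = 2 * 100 + 50  # index of the QTL marker
        donor_excess += all(
            scan.iloc[j][f"d_{p.population_id}"] > 0 for p in pops
        )
    return {
        "coverage_rate": covered / n_replicates,
        "donor_excess_rate": donor_excess / n_replicates,
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# founder association scan: calibration and power

def _assoc_design(sizes: list[int]) -> np.ndarray:
    """Fixed effects: intercept + population indicators."""
    n = sum(sizes)
    cols = [np.ones(n)]
    for i in range(1, len(sizes)):
        c = np.zeros(n)
        start = sum(sizes[:i])
        c[start : start + sizes[i]] = 1.0
        cols.append(c)
    return np.column_stack(cols)


def association_calibration_study(seed: int, n_replicates: int = 50) -> dict:
    """Genomic-control lambda of the scan under a no-genetic-effect null.

    Phenotypes are population means plus iid noise (no marker has an
    effect); 504 markers, 200 lines.  Reports the median over replicates of
    the per-replicate genomic-control lambda and the pooled tail behavior.
    """
    cfg = simulate.SimConfig(
        n_chromosomes=12,
        n_markers_per_chrom=42,
        n_lines=(67, 67, 66),
        selection=None,
        n_selected=None,
        seed=seed,
    )
    markers = simulate.build_marker_map(cfg)
    rng = np.random.default_rng(seed)
    lams = []
    tail05 = 0
    total = 0
    for _ in range(n_replicates):
        pops = [
            simulate.breed_population(cfg, d, rng, markers=markers)[0]
            for d in cfg.donors
        ]
        Z, founders, line_ids = founder_indicators(pops)
        X = _assoc_design([p.n_lines for p in pops])
        y = X @ np.array([12.7, 0.5, -0.3]) + rng.normal(0.0, 1.0, len(line_ids))
        scan = association.association_scan(y, X, None, Z, markers, founders)
        pv = scan.loc[~scan["skipped"], "p_value"].to_numpy()
        lams.append(
            float(np.median(stats.chi2.isf(pv, 1)) / stats.chi2.isf(0.5, 1))
        )
        tail05 += int((pv < 0.05).sum())
        total += pv.size
    return {
        "lambda_median": float(np.median(lams)),
        "fraction_p_below_0.05": tail05 / total,
        "n_replicates": n_replicates,
    }


_ASSOC_QTL_CHROM = 3
_ASSOC_QTL_POS = 15_150_001


def _assoc_effect_size(pve: float = 0.15, h2: float = 0.5) -> float:
    """Per-allele donor deficit giving the target total PVE.

    All three donor alleles carry an equal deficit -b against the recurrent
    allele, so the planted QTL variance is entirely within populations:
    var_qtl = b^2 var_d, var_y = var_qtl + var_poly + var_e with
    var_e = (1-h2)/h2 (var_qtl + var_poly).
    """
    var_d = expected_genotype_freqs(1, 3).dosage_var
    base = simulate.BASELINES["low_nitrogen"]["GY"]
    var_poly = (0.05 * base) ** 2
    c = var_d  # qtl variance coefficient
    tot = c / h2  # contribution of b^2 to var_y (qtl + its share of noise)
    return float(np.sqrt(pve * var_poly / h2 / (c - pve * tot)))


def _assoc_power_config(seed: int) -> simulate.SimConfig:
    b = _assoc_effect_size()
    qtl = simulate.QtlEffect(
        chrom=_ASSOC_QTL_CHROM,
        pos_bp=_ASSOC_QTL_POS,
        trait="GY",
        effects={"low_nitrogen": {"Teqing": -b, "CDR22": -b, "OM1723": -b}},
    )
    return simulate.SimConfig(
        n_chromosomes=12,
        n_markers_per_chrom=100,
        n_lines=(67, 67, 66),
        qtl=(qtl,),
        selection=None,
        n_selected=None,
        heritability={"low_nitrogen": 0.5},
        yield_component_coupling=False,
        seed=seed,
    )


def association_power_study(seed: int, n_replicates: int = 100) -> dict:
    """Detection and founder ranking for a planted low-nitrogen yield QTL.

    One QTL (total PVE 15%) at which every donor allele carries an equal
    deficit against the elite recurrent allele; 200 lines in three
    populations.  Detection = a declared LD block covers the planted
    position at the 1e-4 threshold; ranking = the block peak's
    largest-|effect| founder is the recurrent parent, the founder with the
    largest planted effect.
    """
    cfg = _assoc_power_config(seed)
    markers = simulate.build_marker_map(cfg)
    rng = np.random.default_rng(seed)
    detected = 0
    ranked = 0
    pves = []
    for _ in range(n_replicates):
        poly = simulate._draw_polygenic(markers, rng, scheme=cfg.scheme)
        pairs = [
            simulate.breed_population(
                cfg, d, rng, markers=markers, polygenic_effects=poly
            )
            for d in cfg.donors
        ]
        pops = [p for p, _ in pairs]
        pheno = pd.concat(
            [
                simulate.simulate_phenotypes(
                    p, t, cfg, rng, environments=("low_nitrogen",)
                )
                for p, t in pairs
            ]
        )
        Z, founders, line_ids = founder_indicators(pops)
        y = pheno.groupby("line_id")["GY"].mean().loc[line_ids].to_numpy()
        X = _assoc_design([p.n_lines for p in pops])
        scan = association.association_scan(y, X, None, Z, markers, founders)
        pves.append(float(scan.iloc[2 * 100 + 50]["pve"]))
        dosage = 2.0 - Z[:, :, 0].T
        blocks = association.declare_qtl_blocks(scan, dosage, trait="GY")
        cover = [b for b in blocks if b.covers(_ASSOC_QTL_CHROM, _ASSOC_QTL_POS)]
        if cover:
            detected += 1
            effects = cover[0].effects
            ranked += max(effects, key=lambda f: abs(effects[f])) == cfg.recurrent
    return {
        "detection_rate": detected / n_replicates,
        "founder_ranking_rate": ranked / detected if detected else 0.0,
        "mean_pve_at_qtl": float(np.mean(pves)),
        "n_replicates": n_replicates,
    }


# --------------------------------------------------------------------------
# oracle equivalences and closed-form properties

def oracle_checks(seed: int) -> dict:
    """Independent-oracle agreements on toy data.

    Kinship vs a brute-force double loop on a 5-line x 20-locus toy, and the
    single-population goodness-of-fit chi-square against direct arithmetic
    for counts (10, 2, 20) under the BC1F4 expectation.
    """
    rng = np.random.default_rng(seed)
    cfg = simulate.SimConfig(
        n_chromosomes=2,
        n_markers_per_chrom=10,
        n_lines=(5,),
        donors=("Teqing",),
        selection=None,
        n_selected=None,
        seed=seed,
    )
    markers = simulate.build_marker_map(cfg)
    pop, _ = simulate.breed_population(cfg, "Teqing", rng, markers=markers)
    Z, _, _ = founder_indicators([pop])
    K = association.kinship_from_indicators(Z)
    m, n, F = Z.shape
    K_brute = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K_brute[i, j] = sum(Z[k, i] @ Z[k, j] for k in range(m)) / (2 * m)
    chi2, df, _ = msd.msd_test_single((10, 2, 20), expected_genotype_freqs(1, 3))
    chi2_direct = 169 / 23 + 0 / 2 + 169 / 7
    return {
        "kinship_max_abs_diff": float(np.max(np.abs(K - K_brute))),
        "pearson_chi2_10_2_20": chi2,
        "pearson_chi2_direct": chi2_direct,
        "pearson_chi2_df": df,
    }


def welch_null_rejection(seed: int, n_replicates: int = 10_000) -> dict:
    """Type-I rate of the two-group Welch test at alpha = 0.05.

    Two groups of 30 standard-normal observations per replicate; rejection
    rate should sit in [0.045, 0.055].
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_replicates, 30))
    b = rng.standard_normal((n_replicates, 30))
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return {
        "rejection_rate_alpha05": float((p < 0.05).mean()),
        "n_replicates": n_replicates,
    }


def background_recovery_study(seed: int, n_lines: int = 10_000) -> dict:
    """Mean recurrent-genome recovery of unselected BC1F4 lines.

    Expectation is 1 - (1/2)^(b+1) = 0.75 for one backcross; reports the
    simulated mean, its standard error and the z-score of the deviation.
    """
    cfg = simulate.SimConfig(
        n_chromosomes=12,
        n_markers_per_chrom=50,
        n_lines=(n_lines,),
        donors=("Teqing",),
        selection=None,
        n_selected=None,
        seed=seed,
    )
    markers = simulate.build_marker_map(cfg)
    rng = np.random.default_rng(seed)
    pop, _ = simulate.breed_population(cfg, "Teqing", rng, markers=markers)
    rec = np.array(
        [pyramiding.background_recovery(pop.genotypes[i]) for i in range(pop.n_lines)]
    )
    se = float(rec.std(ddof=1) / np.sqrt(len(rec)))
    return {
        "mean_recovery": float(rec.mean()),
        "expected": 0.75,
        "se": se,
        "z": float((rec.mean() - 0.75) / se),
        "n_lines": n_lines,
    }
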