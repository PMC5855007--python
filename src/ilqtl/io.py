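"""Readers and writers for the package's tabular formats.

Canonical interchange is tab-separated text, UTF-8, with 1-based bp
positions and ``NA`` for missing genotype calls.  Output files carry a
provenance header of ``#``-prefixed lines (version, seed, config hash,
timestamp); the timestamp line is excluded when comparing files for
determinism.  A minimal VCF ingest is provided for convenience: the
recurrent parent must be included as a sample, and its allele defines the
``A`` code.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import CODE_LETTERS, GENOTYPE_CODES, MarkerMap, Population
from .pyramiding import QtlTarget
from .core import CODE_A, CODE_B

__all__ = [
    "read_marker_map",
    "write_marker_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_targets",
    "write_results",
    "read_vcf_genotypes",
]


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"line_id": str})


def write_marker_map(markers: MarkerMap, path) -> None:
    markers.table[["marker_id", "chrom", "pos_bp", "cM"]].to_csv(
        path, sep="\t", index=False
    )


def read_marker_map(path) -> MarkerMap:
    t = _read_table(path)
    required = {"marker_id", "chrom", "pos_bp", "cM"}
    if not required <= set(t.columns):
        raise ValueError(f"{path}: marker map must have columns {sorted(required)}")
    return MarkerMap(t)


def write_genotypes(population: Population, path) -> None:
    """Genotype matrix: first column line_id, one column per marker, A/H/B/NA.

    A provenance header records the population's identity and breeding
    scheme so the file can be re-read without side information.
    """
    path = Path(path)
    letters = np.vectorize(CODE_LETTERS.get)(population.genotypes)
    df = pd.DataFrame(letters, columns=population.markers.marker_ids)
    df.insert(0, "line_id", population.line_ids)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ilqtl v{__version__} genotypes\n")
        fh.write(f"# population_id: {population.population_id}\n")
        fh.write(f"# recurrent: {population.recurrent_id}\n")
        fh.write(f"# donor: {population.donor_id}\n")
        fh.write(f"# scheme: b={population.scheme[0]},s={population.scheme[1]}\n")
        df.to_csv(fh, sep="\t", index=False)


def _header_fields(path) -> dict[str, str]:
    fields = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                fields[key.strip()] = val.strip()
    return fields


def read_genotypes(
    path,
    markers: MarkerMap,
    population_id: str | None = None,
    recurrent_id: str | None = None,
    donor_id: str | None = None,
    scheme: tuple[int, int] | None = None,
) -> Population:
    """Read a genotype matrix and validate it against the marker map.

    Identity and scheme default to the file's provenance header; explicit
    arguments override it.  Unknown genotype codes raise an error naming the
    file, row and column; marker-set mismatches list the first 10 offenders.
    """
    path = Path(path)
    head = _header_fields(path)
    # genotype codes are strings; keep the literal "NA" out of pandas' hands
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.columns[0] != "line_id":
        raise ValueError(f"{path}: first column must be 'line_id'")
    file_markers = list(df.columns[1:])
    expected = markers.marker_ids
    if file_markers != expected:
        if set(file_markers) == set(expected):
            df = df[["line_id"] + expected]
            file_markers = expected
        else:
            offenders = [m for m in file_markers if m not in set(expected)]
            offenders += [m for m in expected if m not in set(file_markers)]
            raise ValueError(
                f"{path}: genotype columns do not match the marker map; "
                f"first offenders: {offenders[:10]}"
            )
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    flat = pd.Series(raw.ravel()).astype(str)
    codes = flat.map(GENOTYPE_CODES)
    if codes.isna().any():
        pos = int(codes.index[codes.isna()][0])
        i, j = divmod(pos, raw.shape[1])
        raise ValueError(
            f"{path}: unknown genotype code {flat.iloc[pos]!r} at "
            f"line {df.iloc[i, 0]!r} (row {i + 2}), marker {file_markers[j]!r}"
        )
    matrix = codes.to_numpy(dtype=np.int8).reshape(raw.shape)
    if scheme is None:
        sch = head.get("scheme", "b=1,s=3")
        parts = dict(kv.split("=") for kv in sch.split(","))
        scheme = (int(parts["b"]), int(parts["s"]))
    return Population(
        population_id=population_id or head.get("population_id", path.stem),
        recurrent_id=recurrent_id or head.get("recurrent", "recurrent"),
        donor_id=donor_id or head.get("donor", "donor"),
        scheme=scheme,
        line_ids=df["line_id"].astype(str).tolist(),
        genotypes=matrix,
        markers=markers,
    )


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path)
    required = {"line_id", "environment"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: phenotypes must have columns {sorted(required)}")
    return df


def read_targets(path) -> list[QtlTarget]:
    """Target-QTL table: qtl, chrom, left_marker, right_marker,
    favorable_founder, favorable_code (A/B), trait, environment."""
    df = _read_table(path)
    targets = []
    for _, r in df.iterrows():
        code = str(r.get("favorable_code", "B")).strip()
        targets.append(
            QtlTarget(
                name=str(r["qtl"]),
                chrom=int(r["chrom"]),
                left_marker=str(r["left_marker"]),
                right_marker=str(r["right_marker"]),
                favorable_founder=str(r.get("favorable_founder", "")),
                favorable_code=CODE_A if code == "A" else CODE_B,
                trait=str(r.get("trait", "GY")),
                environment=str(r.get("environment", "drought")),
            )
        )
    return targets


def write_results(
    records: pd.DataFrame,
    path,
    kind: str,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """Write a result table with a provenance header.

    Deterministic column order (as given); re-running with identical inputs
    produces byte-identical files except for the timestamp line.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ilqtl v{__version__} {kind}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash: {config_hash}\n")
        fh.write(f"# timestamp: {datetime.datetime.now().isoformat()}\n")
        records.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return _read_table(path)


def qtl_records_frame(records) -> pd.DataFrame:
    """Flatten QTLRecord objects into a result table."""
    rows = []
    for r in records:
        row = {
            "qtl": r.name,
            "trait": r.trait,
            "chrom": r.chrom,
            "bin_interval": f"{r.bin_start}-{r.bin_end}",
            "pos_start_bp": r.pos_start_bp,
            "pos_end_bp": r.pos_end_bp,
            "peak_marker": r.peak_marker,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "favorable_source": ",".join(r.favorable_source),
        }
        if r.pve is not None:
            row["pve"] = r.pve
        for founder, eff in r.effects.items():
            row[f"effect_{founder}"] = eff
        rows.append(row)
    return pd.DataFrame(rows)


def read_vcf_genotypes(path, recurrent_sample: str, markers: MarkerMap | None = None):
    """Optional VCF ingest: map the recurrent parent's allele to ``A``.

    Requires pysam.  Only biallelic SNPs with a homozygous call in
    ``recurrent_sample`` are used.  Returns ``(MarkerMap, line_ids, matrix)``
    with genotypes coded as donor-allele dosage.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF ingest requires pysam (pip install ilqtl[vcf])") from exc

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if recurrent_sample not in samples:
        raise ValueError(f"recurrent sample {recurrent_sample!r} not in VCF")
    lines = [s for s in samples if s != recurrent_sample]
    rows, genos = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        rgt = rec.samples[recurrent_sample]["GT"]
        if rgt is None or None in rgt or rgt[0] != rgt[1]:
            continue
        rec_allele = rgt[0]
        calls = np.full(len(lines), -1, dtype=np.int8)
        for i, s in enumerate(lines):
            gt = rec.samples[s]["GT"]
            if gt is None or None in gt:
                continue
            calls[i] = sum(1 for a in gt if a != rec_allele)
        try:
            chrom = int(str(rec.chrom).lstrip("chrChr"))
        except ValueError:
            continue
        rows.append((rec.id or f"{rec.chrom}_{rec.pos}", chrom, rec.pos, rec.pos / 1e6))
        genos.append(calls)
    mm = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "cM"]))
    return mm, lines, np.stack(genos, axis=1)
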