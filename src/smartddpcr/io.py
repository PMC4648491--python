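"""Readers and writers for the documented CSV/TSV dialects.

Every dialect is headered; required columns are validated by name and
unknown columns on well tables are carried through round-trips.  All
coordinates in region/catalog tables are 1-based inclusive; BED input is
converted from 0-based half-open at the reader boundary.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .droplet import DropletWell
from .errors import ValidationError
from .scan import GwasSnp, ScnaRegion

WELL_COLUMNS = (
    "well_id",
    "sample_id",
    "assay_id",
    "n_total",
    "n_fam_pos",
    "n_vic_pos",
    "droplet_volume_ul",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def read_wells_csv(path: str | Path) -> list[DropletWell]:
    """Read droplet wells; extra columns are preserved on each record."""
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, WELL_COLUMNS, path)
    extra_cols = [c for c in df.columns if c not in WELL_COLUMNS]
    wells = []
    for _, row in df.iterrows():
        try:
            well = DropletWell(
                well_id=row["well_id"],
                sample_id=row["sample_id"],
                assay_id=row["assay_id"],
                n_total=int(row["n_total"]),
                n_fam_pos=int(row["n_fam_pos"]),
                n_vic_pos=int(row["n_vic_pos"]),
                droplet_volume_ul=float(row["droplet_volume_ul"]),
                extras={c: row[c] for c in extra_cols},
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: well {row['well_id']!r}: {exc}") from exc
        wells.append(well)
    return wells


def write_wells_csv(path: str | Path, wells: Iterable[DropletWell]) -> None:
    wells = list(wells)
    extra_cols: list[str] = []
    for w in wells:
        for c in w.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(WELL_COLUMNS) + extra_cols)
        for w in wells:
            writer.writerow(
                [
                    w.well_id,
                    w.sample_id,
                    w.assay_id,
                    w.n_total,
                    w.n_fam_pos,
                    w.n_vic_pos,
                    repr(w.droplet_volume_ul),
                ]
                + [w.extras.get(c, "") for c in extra_cols]
            )


def wells_to_csv_text(wells: Iterable[DropletWell]) -> str:
    """Wells dialect as an in-memory string (used by packaged fixtures)."""
    import io as _io

    buf = _io.StringIO()
    buf.write(",".join(WELL_COLUMNS) + "\r\n")
    for w in wells:
        buf.write(
            f"{w.well_id},{w.sample_id},{w.assay_id},{w.n_total},"
            f"{w.n_fam_pos},{w.n_vic_pos},{w.droplet_volume_ul!r}\r\n"
        )
    return buf.getvalue()


def read_samples_csv(path: str | Path) -> dict[str, str]:
    """sample_id -> tissue ("constitutional" / "tumor")."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ("sample_id", "tissue"), path)
    table = {}
    for _, row in df.iterrows():
        tissue = row["tissue"].strip()
        if tissue not in ("constitutional", "tumor"):
            raise ValidationError(
                f"{path}: sample {row['sample_id']!r}: unknown tissue {tissue!r}"
            )
        table[row["sample_id"]] = tissue
    return table


def write_calls_tsv(path: str | Path, rows: Iterable[Mapping]) -> None:
    """AI-call table: sample_id, proportion, sem, status, upper, lower."""
    df = pd.DataFrame(list(rows), columns=["sample_id", "proportion", "sem", "status", "upper", "lower"])
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("sample_id", "proportion", "status"), path)
    return df


def read_mlpa_csv(path: str | Path) -> dict[str, float]:
    """Mean MLPA probe ratio per sample from (sample_id, probe_id, ratio)."""
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "probe_id", "ratio"), path)
    df["ratio"] = df["ratio"].astype(float)
    if not df["ratio"].map(math.isfinite).all():
        raise ValidationError(f"{path}: non-finite MLPA ratio")
    return df.groupby("sample_id")["ratio"].mean().to_dict()


def read_sanger_csv(path: str | Path) -> dict[str, list[tuple[str, float, float]]]:
    """Per-sample (strand, peak_risk, peak_prot) rows."""
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "strand", "peak_risk", "peak_prot"), path)
    out: dict[str, list[tuple[str, float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample_id"]), []).append(
            (str(row["strand"]), float(row["peak_risk"]), float(row["peak_prot"]))
        )
    return out


def read_regions_tsv(path: str | Path) -> list[ScnaRegion]:
    """GISTIC-style peak-region table with 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(
        df, ("peak_name", "chrom", "start", "end", "scna_type", "tumor_types"), path
    )
    regions = []
    for _, row in df.iterrows():
        genes = tuple(g for g in str(row.get("peak_genes", "")).split(",") if g)
        regions.append(
            ScnaRegion(
                peak_name=row["peak_name"],
                cytoband=str(row.get("cytoband", "")),
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                scna_type=row["scna_type"],
                peak_genes=genes,
                tumor_types=tuple(t for t in row["tumor_types"].split(",") if t),
            )
        )
    return regions


def read_regions_bed(path: str | Path, scna_type: str, tumor_types: Sequence[str]) -> list[ScnaRegion]:
    """Minimal BED reader; 0-based half-open converted to 1-based inclusive."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: BED line with < 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            regions.append(
                ScnaRegion(
                    peak_name=name,
                    cytoband="",
                    chrom=chrom,
                    start=start + 1,
                    end=end,
                    scna_type=scna_type,
                    peak_genes=(),
                    tumor_types=tuple(tumor_types),
                )
            )
    return regions


def read_gwas_catalog_tsv(path: str | Path) -> tuple[list[GwasSnp], int]:
    """NHGRI-EBI GWAS-Catalog-style TSV.

    Required columns: CHR_ID, CHR_POS, DISEASE/TRAIT, MAPPED_GENE, SNPS.
    Rows with missing/non-numeric positions or multi-SNP haplotypes are
    skipped; the skipped-row count is returned alongside the SNPs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ("CHR_ID", "CHR_POS", "DISEASE/TRAIT", "MAPPED_GENE", "SNPS"), path)
    snps: list[GwasSnp] = []
    n_skipped = 0
    for _, row in df.iterrows():
        rsid = row["SNPS"].strip()
        pos = row["CHR_POS"].strip()
        chrom = row["CHR_ID"].strip()
        if (
            not rsid
            or not pos.isdigit()
            or not chrom
            or ";" in rsid
            or " x " in rsid
            or ";" in chrom
        ):
            n_skipped += 1
            continue
        genes = tuple(
            g.strip()
            for part in row["MAPPED_GENE"].split(";")
            for g in part.replace(" - ", ",").split(",")
            if g.strip()
        )
        snps.append(
            GwasSnp(
                rsid=rsid,
                chrom=chrom,
                pos=int(pos),
                trait=row["DISEASE/TRAIT"],
                mapped_genes=genes,
            )
        )
    return snps, n_skipped


def read_vocab_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    """trait_phrase -> tumor-type codes mapping (phrases normalized)."""
    from .scan import normalize_trait

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ("trait_phrase", "codes"), path)
    vocab = {}
    for _, row in df.iterrows():
        codes = tuple(c.strip() for c in row["codes"].split(",") if c.strip())
        vocab[normalize_trait(row["trait_phrase"])] = codes
    return vocab


def write_candidates_tsv(path: str | Path, candidates) -> None:
    rows = []
    for cand in candidates:
        rows.append(
            {
                "peak_name": cand.region.peak_name,
                "cytoband": cand.region.cytoband,
                "chrom": cand.region.chrom,
                "start": cand.region.start,
                "end": cand.region.end,
                "scna_type": cand.region.scna_type,
                "tumor_types": ",".join(cand.region.tumor_types),
                "snps": ",".join(s.rsid for s in cand.snps),
                "snp_cancer_types": ",".join(
                    sorted({c for s in cand.snps for c in s.cancer_types})
                ),
                "matched": cand.matched,
                "matched_types": ",".join(cand.matched_types),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_states_tsv(path: str | Path, rows: Iterable[Mapping]) -> None:
    df = pd.DataFrame(
        list(rows),
        columns=[
            "sample_id",
            "proportion",
            "normalized_cn",
            "model",
            "clonal_fraction",
            "residual",
            "ambiguous_flag",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
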