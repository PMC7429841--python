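"""Genotype-matrix container, file formats, and marker-selection filters.

Genotype calls are coded against the two parental alleles: ``a`` (parent-A
homozygote), ``b`` (parent-B homozygote), ``h`` (heterozygote) and ``-``
(missing).  Internally calls are int8 (0/1/2/−1); the characters appear only
in files.  Coordinates are 0-based half-open internally; VCF and GFF3 are
converted at the boundary.

Formats: genotype TSV (marker_id, chrom, pos_bp, one column per sample),
VCF 4.2 (0/0 → a, 1/1 → b, 0/1 → h, ./. → -), map TSV (marker_id,
linkage_group, cm), BED6, GFF3 genes, and a 2-column gene→GO-term mapping
plus a term/aspect/label table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CODE_A",
    "CODE_B",
    "CODE_H",
    "CODE_MISSING",
    "GenotypeMatrix",
    "MarkerFilterError",
    "read_genotypes",
    "write_genotypes",
    "filter_map_markers",
    "filter_panel_markers",
    "read_map",
    "write_map",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_go_mapping",
    "read_go_labels",
]

CODE_A, CODE_B, CODE_H, CODE_MISSING = np.int8(0), np.int8(1), np.int8(2), np.int8(-1)
_CHAR_FOR = {0: "a", 1: "b", 2: "h", -1: "-"}
_CODE_FOR = {"a": CODE_A, "b": CODE_B, "h": CODE_H, "-": CODE_MISSING}


class MarkerFilterError(ValueError):
    """A marker filter left nothing to analyse."""


@dataclass
class GenotypeMatrix:
    """Markers × samples parental genotype calls with physical coordinates.

    ``markers`` has columns marker_id/chrom/pos (0-based bp, non-decreasing
    within each chromosome); ``calls`` is int8 of shape
    (n_markers, n_samples).
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError("calls shape does not match markers × samples")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicated marker_id {dup!r}")
        bad = ~np.isin(self.calls, [CODE_A, CODE_B, CODE_H, CODE_MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call at marker {self.markers['marker_id'].iloc[i]!r}, "
                f"sample {self.samples[j]!r}"
            )
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"marker positions not sorted on {chrom}")

    # -- shape -----------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    # -- views -----------------------------------------------------------
    def call_chars(self) -> np.ndarray:
        lut = np.array(["-", "a", "b", "h"])  # index by code+1
        return lut[self.calls.astype(np.int64) + 1]

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == CODE_MISSING).mean(axis=1)

    def chrom_slice(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, calls) restricted to one chromosome."""
        mask = (self.markers["chrom"] == chrom).to_numpy()
        return self.markers.loc[mask, "pos"].to_numpy(), self.calls[mask]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.markers.loc[np.asarray(mask)], list(self.samples), self.calls[np.asarray(mask)])

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.markers.reset_index(drop=True).equals(other.markers.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# genotype matrix I/O
# ---------------------------------------------------------------------------


def write_genotypes(gm: GenotypeMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        chars = gm.call_chars()
        out = pd.concat(
            [
                gm.markers.rename(columns={"pos": "pos_bp"}),
                pd.DataFrame(chars, columns=gm.samples, index=gm.markers.index),
            ],
            axis=1,
        )
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "vcf":
        _write_vcf(gm, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    fixed = ["marker_id", "chrom", "pos_bp"]
    missing_cols = [c for c in fixed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {missing_cols}")
    samples = [c for c in df.columns if c not in fixed]
    markers = df[fixed].rename(columns={"pos_bp": "pos"})
    markers["pos"] = markers["pos"].astype(np.int64)
    calls = np.empty((len(df), len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        col = df[s].astype(str).to_numpy()
        for i, ch in enumerate(col):
            code = _CODE_FOR.get(ch)
            if code is None:
                raise ValueError(
                    f"{path}: unknown call {ch!r} at marker "
                    f"{df['marker_id'].iloc[i]!r}, sample {s!r}"
                )
            calls[i, j] = code
    return GenotypeMatrix(markers, samples, calls)


_VCF_GT = {0: "0/0", 1: "1/1", 2: "0/1", -1: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=recohot\n")
        for chrom, grp in gm.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_markers):
            row = gm.markers.iloc[i]
            gts = "\t".join(_VCF_GT[int(c)] for c in gm.calls[i])
            fh.write(f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['marker_id']}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([CODE_A, CODE_H, CODE_MISSING, CODE_B], dtype=np.int8)
    for v in vcf:
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        rows.append(gt_map[np.asarray(v.gt_types)])
    vcf.close()
    markers = pd.DataFrame({"marker_id": ids, "chrom": chroms, "pos": np.array(poss, dtype=np.int64)})
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(markers, samples, calls)


# ---------------------------------------------------------------------------
# marker-selection filters
# ---------------------------------------------------------------------------


def filter_map_markers(gm: GenotypeMatrix, max_missing: float = 0.05) -> GenotypeMatrix:
    """Keep markers whose missing fraction is ≤ ``max_missing`` (inclusive).

    The map-construction filter: the study retained markers with at most 5%
    missing data for linkage mapping.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    keep = gm.missing_fraction() <= max_missing + 1e-12
    return gm.subset_markers(keep)


def filter_panel_markers(gm: GenotypeMatrix, min_call: float = 0.8, min_maf: float = 0.05) -> GenotypeMatrix:
    """Panel filter: call frequency strictly > ``min_call`` and MAF strictly
    > ``min_maf``.

    MAF is computed from allele counts with a heterozygote contributing one
    copy of each allele.  Markers with every call missing are dropped (call
    frequency 0), never an error.
    """
    if not (0 < min_call < 1 and 0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    called = gm.calls != CODE_MISSING
    call_freq = called.mean(axis=1)
    n_a = 2 * (gm.calls == CODE_A).sum(axis=1) + (gm.calls == CODE_H).sum(axis=1)
    n_b = 2 * (gm.calls == CODE_B).sum(axis=1) + (gm.calls == CODE_H).sum(axis=1)
    total = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(n_a, n_b) / np.maximum(total, 1), 0.0)
    keep = (call_freq > min_call) & (maf > min_maf)
    return gm.subset_markers(keep)


# ---------------------------------------------------------------------------
# map files, BED, GFF3, GO tables
# ---------------------------------------------------------------------------


def write_map(map_df: pd.DataFrame, path) -> None:
    map_df[["marker_id", "linkage_group", "cm"]].to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "linkage_group": str})
    for lg, grp in df.groupby("linkage_group", sort=False):
        if not grp["cm"].is_monotonic_increasing:
            raise ValueError(f"cM positions not non-decreasing in group {lg}")
    return df


def write_bed(df: pd.DataFrame, path, name_col: str = "name", score_col: str | None = None) -> None:
    """Write chrom/start/end plus BED6 name, score, strand columns."""
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = df[name_col] if name_col in df.columns else "."
    out["score"] = df[score_col] if score_col and score_col in df.columns else 0
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as gene_id/chrom/start/end/strand.

    GFF3's 1-based inclusive spans are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True, force=True
    )
    rows = []
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("ID", [f.id])[0]
        rows.append((gid, f.seqid, f.start - 1, f.end, f.strand or "."))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\trecohot\tgene\t{int(g['start']) + 1}\t{int(g['end'])}\t.\t"
                f"{g.get('strand', '.')}\t.\tID={g['gene_id']}\n"
            )


def read_go_mapping(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str, comment="#")
    return df.drop_duplicates()


def read_go_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"term_id", "aspect", "label"}
    if not need.issubset(df.columns):
        raise ValueError(f"GO label table must have columns {sorted(need)}")
    bad = ~df["aspect"].isin(["BP", "CC", "MF"])
    if bad.any():
        raise ValueError(f"invalid GO aspect {df.loc[bad, 'aspect'].iloc[0]!r}")
    return df
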