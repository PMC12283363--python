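"""File formats: VCF in/out, truth and result TSV/BED writers.

Coordinate conventions: VCF and TSV outputs are 1-based closed; BED outputs
are 0-based half-open.  Every writer states the convention and the column
meaning in a ``#``-prefixed header.  Reading uses cyvcf2; only biallelic
SNVs are loaded (others are counted and skipped) and genotypes map as
0/0 -> HOM_COL, 0/1 or 1/0 -> HET, 1/1 -> HOM_LER, ./. -> MISSING, with a
missing DP treated as depth 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import HET, HOM_COL, HOM_LER, MISSING, GenotypeMatrix

log = logging.getLogger("xomap")

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_truth_tsv",
    "read_truth_tsv",
    "events_to_frame",
    "write_events_tsv",
    "write_events_bed",
]

_GT = {int(HOM_COL): "0/0", int(HET): "0/1", int(HOM_LER): "1/1", int(MISSING): "./."}


def write_vcf(gm: GenotypeMatrix, path, specs=None, extra_header=()):
    """Write the matrix as an uncompressed multi-sample VCF (GT:DP).

    Positions are 1-based; one ``##contig`` line per chromosome (lengths from
    ``specs`` when given, else the last marker position).
    """
    lengths = {}
    if specs:
        lengths = {s.name: s.length_bp for s in specs}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xomap\n")
        for line in extra_header:
            fh.write(f"##{line}\n")
        for chrom in gm.chromosomes:
            length = lengths.get(chrom, int(gm.markers.loc[gm.markers["chrom"] == chrom, "pos"].max()))
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        ref = gm.markers.get("ref", pd.Series(["A"] * gm.n_markers))
        alt = gm.markers.get("alt", pd.Series(["C"] * gm.n_markers))
        for j in range(gm.n_markers):
            fields = [
                str(gm.markers["chrom"].iloc[j]),
                str(int(gm.markers["pos"].iloc[j])),
                ".",
                str(ref.iloc[j]),
                str(alt.iloc[j]),
                ".",
                "PASS",
                ".",
                "GT:DP",
            ]
            fields += [f"{_GT[int(gm.calls[i, j])]}:{int(gm.depth[i, j])}" for i in range(gm.n_samples)]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, return_stats=False):
    """Load a multi-sample VCF (GT, DP per genotype) into a GenotypeMatrix.

    Non-biallelic or non-SNV records are skipped and counted; malformed
    genotypes count as MISSING.  Unsorted positions within a contig are
    rejected.  With ``return_stats`` a ``(matrix, stats)`` tuple is returned.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    call_cols, depth_cols = [], []
    stats = {"loaded": 0, "skipped_multiallelic": 0, "skipped_non_snv": 0}
    last_pos = {}
    for v in vcf:
        if len(v.ALT) != 1:
            stats["skipped_multiallelic"] += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            stats["skipped_non_snv"] += 1
            continue
        if v.CHROM in last_pos and v.POS <= last_pos[v.CHROM]:
            raise ValueError(f"unsorted VCF: {v.CHROM}:{v.POS} after {last_pos[v.CHROM]}")
        last_pos[v.CHROM] = v.POS
        gts = v.genotypes  # [a0, a1, phased] per sample
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            elif a == 0 and b == 0:
                col[i] = HOM_COL
            elif a == 1 and b == 1:
                col[i] = HOM_LER
            else:
                col[i] = HET
        dp = v.format("DP")
        if dp is None:
            dcol = np.zeros(len(samples), dtype=np.int32)
        else:
            dcol = np.asarray(dp, dtype=float).reshape(len(samples))
            dcol = np.where(np.isfinite(dcol) & (dcol >= 0), dcol, 0).astype(np.int32)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        call_cols.append(col)
        depth_cols.append(dcol)
        stats["loaded"] += 1
    markers = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = np.array(call_cols, dtype=np.int8).T if call_cols else np.zeros((len(samples), 0), np.int8)
    depth = np.array(depth_cols, dtype=np.int32).T if depth_cols else np.zeros((len(samples), 0), np.int32)
    gm = GenotypeMatrix(samples=samples, markers=markers, calls=calls, depth=depth)
    if stats["skipped_multiallelic"] or stats["skipped_non_snv"]:
        log.warning(
            "read_vcf: skipped %d multiallelic and %d non-SNV records",
            stats["skipped_multiallelic"],
            stats["skipped_non_snv"],
        )
    return (gm, stats) if return_stats else gm


def write_truth_tsv(truths, path):
    """True transmitted CO positions, one row per (sample, chromosome)."""
    with open(path, "w") as fh:
        fh.write("# true transmitted crossover positions; 1-based bp, comma-separated\n")
        fh.write("sample\tchrom\tstart_parent\tco_bp\n")
        for t in truths:
            for chrom in t.co_bp:
                cos = ",".join(str(int(p)) for p in t.co_bp[chrom])
                fh.write(f"{t.sample_id}\t{chrom}\t{t.start_parent[chrom]}\t{cos}\n")


def read_truth_tsv(path):
    from .simulate import TrueGamete

    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for row in df.itertuples(index=False):
        g = out.setdefault(row.sample, TrueGamete(sample_id=row.sample))
        cos = [] if pd.isna(row.co_bp) or row.co_bp == "" else [int(x) for x in str(row.co_bp).split(",")]
        g.co_bp[row.chrom] = np.asarray(cos, dtype=np.int64)
        g.start_parent[row.chrom] = int(row.start_parent)
    return list(out.values())


def events_to_frame(events) -> pd.DataFrame:
    rows = [
        {
            "sample": ev.sample,
            "chrom": ev.chrom,
            "left_bp": ev.left_bp,
            "right_bp": ev.right_bp,
            "mid_bp": ev.mid_bp,
            "left_genotype": ev.left_genotype,
            "right_genotype": ev.right_genotype,
        }
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "chrom", "left_bp", "right_bp", "mid_bp", "left_genotype", "right_genotype"],
    )


def write_events_tsv(events, path, header_lines=()):
    df = events_to_frame(events)
    with open(path, "w") as fh:
        fh.write("# called crossovers; left_bp/right_bp/mid_bp are 1-based closed coordinates\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_events_bed(events, path, header_lines=()):
    """BED: chrom, left_bp-1, right_bp, sample, mid_bp (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("# BED (0-based half-open): chrom start end sample mid_bp\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        for ev in events:
            fh.write(f"{ev.chrom}\t{ev.left_bp - 1}\t{ev.right_bp}\t{ev.sample}\t{ev.mid_bp}\n")
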