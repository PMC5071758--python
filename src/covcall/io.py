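"""Readers/writers for the artifact's on-disk formats.

Truth panels and call sets travel as VCF 4.2 (via pysam), region annotations
as 4-column BED (0-based half-open, class name in column 4), pileups as a
TSV dialect with one row per site x sample: chrom, pos (1-based), sample_id,
bases string, quals string (phred+33). A zero-depth pileup row uses "." for
both strings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .calling import CallSet, NO_CALL
from .evaluate import DEPTH_BIN_LABELS, DepthHistogram
from .simulate import BASES, RegionMap, REGION_CLASSES, SampleData, TruthPanel

_GT_TUPLE = {0: (0, 0), 1: (0, 1), 2: (1, 1), NO_CALL: (None, None)}
_TUPLE_GT = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2, (None, None): NO_CALL}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _base_header(truth: TruthPanel, with_format: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={truth.chrom},length={truth.genome_length}>")
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    if with_format:
        header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                         ("Description", "Read depth")])
        header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", "1"), ("Type", "Integer"),
                                         ("Description", "Genotype quality")])
        header.add_meta("FORMAT", items=[("ID", "PL"), ("Number", "G"), ("Type", "Integer"),
                                         ("Description", "Phred-scaled genotype likelihoods")])
    return header


def write_truth_vcf(truth: TruthPanel, path: str | Path) -> None:
    """Truth genotypes as a VCF with one sample column per individual."""
    header = _base_header(truth, with_format=False)
    for sid in truth.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(len(truth)):
            rec = vf.new_record(
                contig=truth.chrom,
                start=int(truth.pos[i]) - 1,
                alleles=(BASES[truth.ref[i]], BASES[truth.alt[i]]),
            )
            for s, sid in enumerate(truth.sample_ids):
                rec.samples[sid]["GT"] = _GT_TUPLE[int(truth.genotypes[s, i])]
            vf.write(rec)


def read_truth_vcf(path: str | Path) -> TruthPanel:
    """Rebuild a truth panel (regions unset) from :func:`write_truth_vcf` output."""
    pos, ref, alt, gts = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = tuple(vf.header.samples)
        contigs = list(vf.header.contigs.values())
        chrom = contigs[0].name if contigs else "chr1"
        length = contigs[0].length if contigs and contigs[0].length else 0
        for rec in vf:
            pos.append(rec.pos)
            ref.append(BASES.index(rec.ref))
            alt.append(BASES.index(rec.alts[0]))
            gts.append([_TUPLE_GT[tuple(rec.samples[s]["GT"])] for s in sample_ids])
    genotypes = np.asarray(gts, dtype=np.int8).T if gts else np.zeros((len(sample_ids), 0), np.int8)
    n = len(pos)
    return TruthPanel(
        chrom=chrom,
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=np.int8),
        alt=np.asarray(alt, dtype=np.int8),
        genotypes=genotypes,
        region=np.zeros(n, dtype=np.int8),
        sample_ids=sample_ids,
        genome_length=int(length) or (int(max(pos)) if pos else 0),
    )


def write_calls_vcf(truth: TruthPanel, calls: CallSet, path: str | Path) -> None:
    """Calls as VCF with FORMAT GT:DP:GQ:PL; missing genotypes as ./."""
    header = _base_header(truth, with_format=True)
    for sid in calls.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in range(calls.n_sites):
            rec = vf.new_record(
                contig=truth.chrom,
                start=int(truth.pos[i]) - 1,
                alleles=(BASES[truth.ref[i]], BASES[truth.alt[i]]),
            )
            for s, sid in enumerate(calls.sample_ids):
                smp = rec.samples[sid]
                smp["GT"] = _GT_TUPLE[int(calls.gt[s, i])]
                smp["DP"] = int(calls.dp[s, i])
                smp["GQ"] = int(calls.gq[s, i])
                smp["PL"] = tuple(int(p) for p in calls.pl[s, i])
            vf.write(rec)


def read_calls_vcf(path: str | Path) -> CallSet:
    gt, dp, gq, pl = [], [], [], []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = tuple(vf.header.samples)
        for rec in vf:
            gt.append([_TUPLE_GT[tuple(rec.samples[s]["GT"])] for s in sample_ids])
            dp.append([rec.samples[s]["DP"] for s in sample_ids])
            gq.append([rec.samples[s]["GQ"] for s in sample_ids])
            pl.append([list(rec.samples[s]["PL"]) for s in sample_ids])
    return CallSet(
        sample_ids=sample_ids,
        gt=np.asarray(gt, dtype=np.int8).T,
        dp=np.asarray(dp, dtype=np.int64).T,
        gq=np.asarray(gq, dtype=np.int16).T,
        pl=np.asarray(pl, dtype=np.int64).transpose(1, 0, 2),
        pipeline="unknown",
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_regions_bed(regions: RegionMap, path: str | Path, chrom: str = "chr1") -> None:
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": regions.starts,
            "end": regions.ends,
            "name": [REGION_CLASSES[c] for c in regions.classes],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str | Path) -> RegionMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    classes = np.array([REGION_CLASSES.index(n) for n in df["name"]], dtype=np.int8)
    return RegionMap(
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        classes=classes,
    )


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------

def write_pileups_tsv(data: SampleData, path: str | Path) -> None:
    truth = data.truth
    base_bytes = np.frombuffer(BASES.encode(), dtype=np.uint8)[data.bases]
    qual_bytes = (data.quals + 33).astype(np.uint8)
    depths = data.depths()
    offsets = np.concatenate([[0], np.cumsum(depths)])
    rows = []
    for i in range(len(truth)):
        lo, hi = offsets[i], offsets[i + 1]
        if hi > lo:
            b = bytes(base_bytes[lo:hi]).decode()
            q = bytes(qual_bytes[lo:hi]).decode("latin-1")
        else:
            b = q = "."
        rows.append((truth.chrom, int(truth.pos[i]), data.sample_id, b, q))
    pd.DataFrame(rows, columns=["chrom", "pos", "sample_id", "bases", "quals"]).to_csv(
        path, sep="\t", index=False
    )


def read_pileups_tsv(path: str | Path, truth: TruthPanel, sample_id: str | None = None) -> SampleData:
    df = pd.read_csv(path, sep="\t", dtype={"bases": str, "quals": str})
    if sample_id is None:
        sample_id = str(df["sample_id"].iloc[0])
    pos_to_idx = {int(p): i for i, p in enumerate(truth.pos)}
    site_index, bases, quals = [], [], []
    for pos, b, q in zip(df["pos"], df["bases"], df["quals"]):
        if b == "." or not isinstance(b, str):
            continue
        i = pos_to_idx[int(pos)]
        site_index.extend([i] * len(b))
        bases.extend(BASES.index(c) for c in b)
        quals.extend(ord(c) - 33 for c in q)
    order = np.argsort(np.asarray(site_index, dtype=np.int64), kind="stable")
    return SampleData(
        sample_id=sample_id,
        truth=truth,
        site_index=np.asarray(site_index, dtype=np.int64)[order],
        bases=np.asarray(bases, dtype=np.int8)[order],
        quals=np.asarray(quals, dtype=np.int16)[order],
        depth_track=None,
    )


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

def write_titration_tsv(points, path: str | Path) -> None:
    pd.DataFrame(
        {
            "coverage": [p.coverage for p in points],
            "replicate": [p.replicate for p in points],
            "pipeline": [p.pipeline for p in points],
            "calling_rate": [p.calling_rate for p in points],
            "precision": [np.nan if p.precision is None else p.precision for p in points],
        }
    ).to_csv(path, sep="\t", index=False)


def write_dp_sweep_tsv(points, path: str | Path) -> None:
    pd.DataFrame(
        {
            "evaluation_coverage": [p.evaluation_coverage for p in points],
            "dp_threshold": [p.dp_threshold for p in points],
            "accuracy": [np.nan if p.accuracy is None else p.accuracy for p in points],
            "n_evaluated": [p.n_evaluated for p in points],
        }
    ).to_csv(path, sep="\t", index=False)


def write_depth_histogram_tsv(hists: dict[str, DepthHistogram], path: str | Path) -> None:
    rows = [
        (sid, label, frac)
        for sid, h in hists.items()
        for label, frac in zip(DEPTH_BIN_LABELS, h.fractions)
    ]
    pd.DataFrame(rows, columns=["sample_id", "depth_bin", "fraction"]).to_csv(
        path, sep="\t", index=False
    )


def write_stratified_tsv(rows: list[tuple], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["pipeline", "coverage", "region", "calling_rate"]).to_csv(
        path, sep="\t", index=False
    )
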