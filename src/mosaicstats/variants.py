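"""Somatic call-set IO, mosaic filtering, and context annotation.

A call set is a mapping ``sample_id -> list[VariantRecord]``.  Positions are
1-based throughout; only single-base substitutions are modelled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._contexts import (
    COMPLEMENT,
    collapse_context,
    sbs96_index,
    SBS96_LABELS,
)
from .intervals import IntervalTrack
from .reference import as_seq_dict

logger = logging.getLogger(__name__)

Callset = dict[str, list["VariantRecord"]]


@dataclass
class VariantRecord:
    """One somatic single-nucleotide variant call.

    ``vaf`` is derived from ``alt_reads / total_reads`` when read support is
    present.  ``context`` is the reference 3-mer centred on the variant;
    ``context_pyr``/``substitution`` are its pyrimidine-collapsed form;
    ``dist_tfbs`` is the signed distance (pos - midpoint) to the nearest
    TFBS midpoint once annotated.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int | None = None
    total_reads: int | None = None
    vaf: float | None = None
    pop_af: float | None = None
    context: str | None = None
    context_pyr: str | None = None
    substitution: str | None = None
    is_cpg: bool | None = None
    dist_tfbs: int | None = None
    origin: str | None = field(default=None, repr=False)  # simulator attribution

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt or self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"not an SNV: {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.vaf is None and self.total_reads:
            self.vaf = self.alt_reads / self.total_reads
        if self.vaf is not None and not (0 < self.vaf <= 1):
            raise ValueError(f"VAF {self.vaf} outside (0, 1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def sbs96(self) -> int:
        if self.context_pyr is None:
            raise ValueError("record not context-annotated")
        return sbs96_index(self.context_pyr, self.substitution)


@dataclass
class FilterParams:
    """Post-calling mosaic filters.

    Defaults: VAF cap 0.40 (germline heterozygote guard), exact binomial
    test of the VAF against 0.5 at p < 1e-6 (the call must be significantly
    non-germline), population allele frequency <= 0.001, and at least 4
    supporting alt reads.
    """

    vaf_max: float = 0.40
    germline_p_threshold: float = 1e-6
    pop_af_max: float = 0.001
    min_alt_reads: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.vaf_max <= 1 and 0 < self.germline_p_threshold < 1
                and 0 <= self.pop_af_max <= 1 and self.min_alt_reads >= 0):
            raise ValueError("filter thresholds out of range")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "alt_reads", "total_reads"]


def read_callset(paths, fmt: str | None = None) -> Callset:
    """Read per-sample VCFs and/or a combined TSV into a call set.

    ``paths`` is a path or list of paths.  ``.vcf``/``.vcf.gz`` files are
    parsed with pysam (sample id taken from the filename stem unless the
    file carries a single sample column); anything else is read as TSV with
    columns sample_id, chrom, pos, ref, alt, alt_reads, total_reads and
    optionally pop_af.  Multi-allelic rows are split; non-SNV alleles are
    skipped and counted.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    callset: Callset = {}
    skipped = 0
    for path in paths:
        path = Path(path)
        is_vcf = fmt == "vcf" or (fmt is None and ".vcf" in path.suffixes or path.suffix == ".vcf")
        if is_vcf:
            skipped += _read_vcf(path, callset)
        else:
            skipped += _read_tsv(path, callset)
    if skipped:
        logger.info("skipped %d non-SNV alleles", skipped)
    for records in callset.values():
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    return callset


def _read_vcf(path: Path, callset: Callset) -> int:
    import pysam

    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        default_sample = samples[0] if len(samples) == 1 else path.name.split(".")[0]
        for rec in vf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt \
                        or rec.ref not in "ACGT" or alt not in "ACGT":
                    skipped += 1
                    continue
                info = rec.info

                def _get(key):
                    try:
                        return info.get(key)
                    except (KeyError, ValueError):
                        return None

                dp = _get("DP")
                ad = _get("AD")
                alt_reads = total = None
                if ad is not None:
                    ad = ad if isinstance(ad, (tuple, list)) else (ad,)
                    if len(ad) >= 2:
                        alt_reads, total = int(ad[1]), int(ad[0]) + int(ad[1])
                    else:
                        alt_reads = int(ad[0])
                if total is None and dp is not None:
                    total = int(dp)
                vaf = _get("VAF")
                if isinstance(vaf, (tuple, list)):
                    vaf = vaf[0]
                pop_af = _get("POP_AF")
                callset.setdefault(default_sample, []).append(
                    VariantRecord(
                        sample_id=default_sample, chrom=rec.chrom, pos=rec.pos,
                        ref=rec.ref, alt=alt, alt_reads=alt_reads,
                        total_reads=total, vaf=float(vaf) if vaf is not None else None,
                        pop_af=float(pop_af) if pop_af is not None else None,
                    )
                )
    return skipped


def _read_tsv(path: Path, callset: Callset) -> int:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_TSV_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    skipped = 0
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            skipped += 1
            continue
        try:
            rec = VariantRecord(
                sample_id=str(row.sample_id), chrom=str(row.chrom), pos=int(row.pos),
                ref=ref, alt=alt,
                alt_reads=int(row.alt_reads) if hasattr(row, "alt_reads") and pd.notna(row.alt_reads) else None,
                total_reads=int(row.total_reads) if hasattr(row, "total_reads") and pd.notna(row.total_reads) else None,
                pop_af=float(row.pop_af) if hasattr(row, "pop_af") and pd.notna(row.pop_af) else None,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
        callset.setdefault(rec.sample_id, []).append(rec)
    return skipped


def callset_to_frame(callset: Callset) -> pd.DataFrame:
    """Flatten a call set into a tidy DataFrame (one row per record)."""
    rows = []
    for sample, records in callset.items():
        for r in records:
            rows.append({
                "sample_id": sample, "chrom": r.chrom, "pos": r.pos,
                "ref": r.ref, "alt": r.alt, "alt_reads": r.alt_reads,
                "total_reads": r.total_reads, "vaf": r.vaf, "pop_af": r.pop_af,
                "context": r.context, "context_pyr": r.context_pyr,
                "substitution": r.substitution, "is_cpg": r.is_cpg,
                "dist_tfbs": r.dist_tfbs, "origin": r.origin,
            })
    return pd.DataFrame(rows)


def write_callset_tsv(callset: Callset, path: str | Path) -> None:
    frame = callset_to_frame(callset)
    cols = [c for c in _TSV_COLUMNS + ["pop_af", "vaf", "origin"] if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

FILTER_ORDER = ("vaf_max", "germline_p", "pop_af", "min_reads")


def apply_mosaic_filters(
    callset: Callset, params: FilterParams | None = None
) -> tuple[Callset, pd.DataFrame]:
    """Apply the mosaic post-calling filters in a fixed order.

    A record is kept iff VAF <= ``vaf_max``, the exact two-sided binomial
    test of alt/total against 0.5 rejects at ``germline_p_threshold``
    (i.e. the VAF is significantly below a germline heterozygote's), its
    population allele frequency (missing treated as 0, i.e. novel) is
    <= ``pop_af_max``, and alt reads >= ``min_alt_reads``.  Removals are
    labelled with the first failing rule in that fixed order.

    Returns ``(kept_callset, removed)`` where ``removed`` is a DataFrame
    with a ``reason`` column.
    """
    params = params or FilterParams()
    kept: Callset = {}
    removed_rows = []
    for sample, records in callset.items():
        kept[sample] = []
        for r in records:
            reason = _first_failure(r, params)
            if reason is None:
                kept[sample].append(r)
            else:
                removed_rows.append({
                    "sample_id": sample, "chrom": r.chrom, "pos": r.pos,
                    "ref": r.ref, "alt": r.alt, "vaf": r.vaf, "reason": reason,
                })
    removed = pd.DataFrame(removed_rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "vaf", "reason"])
    return kept, removed


def _first_failure(r: VariantRecord, p: FilterParams) -> str | None:
    if r.vaf is None:
        raise ValueError(f"record {r.chrom}:{r.pos} has no VAF")
    if r.vaf > p.vaf_max:
        return "vaf_max"
    if r.total_reads is not None:
        if r.total_reads == 0:
            raise ValueError(f"record {r.chrom}:{r.pos} has zero total reads")
        pval = stats.binomtest(r.alt_reads, r.total_reads, 0.5).pvalue
        if pval >= p.germline_p_threshold:
            return "germline_p"
    else:
        warnings.warn("no read counts; germline binomial filter skipped", stacklevel=3)
    if (r.pop_af or 0.0) > p.pop_af_max:
        return "pop_af"
    if r.alt_reads is not None and r.alt_reads < p.min_alt_reads:
        return "min_reads"
    return None


# ---------------------------------------------------------------------------
# Context annotation and spectra
# ---------------------------------------------------------------------------

def annotate_context(callset: Callset, reference) -> Callset:
    """Annotate each record with its trinucleotide context (in place).

    Adds ``context`` (reference 3-mer), ``context_pyr``/``substitution``
    (pyrimidine-collapsed) and ``is_cpg`` (the mutated C sits in a CG
    dinucleotide on either strand).  Raises if the reference base at the
    variant position disagrees with the record's ref allele.
    """
    seqs = as_seq_dict(reference)
    for records in callset.values():
        for r in records:
            seq = seqs[r.chrom]
            if not (2 <= r.pos <= len(seq) - 1):
                raise ValueError(f"{r.chrom}:{r.pos}: no flanking base inside contig")
            tri = seq[r.pos - 2: r.pos + 1].upper()
            if tri[1] != r.ref:
                raise ValueError(
                    f"{r.chrom}:{r.pos}: reference base {tri[1]} != ref allele {r.ref}")
            r.context = tri
            r.context_pyr, r.substitution = collapse_context(tri, r.ref, r.alt)
            r.is_cpg = r.context_pyr[1] == "C" and r.context_pyr[2] == "G"
    return callset


def spectrum_96(callset: Callset) -> pd.Series:
    """96-channel substitution spectrum (counts; index = channel labels)."""
    counts = np.zeros(96, dtype=np.int64)
    for records in callset.values():
        for r in records:
            if r.context_pyr is None:
                raise ValueError(f"unannotated record {r.chrom}:{r.pos}")
            counts[r.sbs96] += 1
    return pd.Series(counts, index=SBS96_LABELS, name="count")


# ---------------------------------------------------------------------------
# Track overlap and distances
# ---------------------------------------------------------------------------

def overlap_counts(
    callset: Callset, track: IntervalTrack, reference=None, base_subset: str | None = None
):
    """Count in-track variants and, optionally, the track's site census.

    A variant falls in an interval iff ``start <= pos <= end`` (1-based
    inclusive).  Returns ``(total, per_sample, census)`` where ``census`` is
    the number of reference bases in the merged track (restricted to
    ``base_subset``, e.g. ``"TA"``, when given); ``census`` is None when no
    reference is supplied.
    """
    merged = track.merge()
    per_sample: dict[str, int] = {}
    for sample, records in callset.items():
        if not records:
            per_sample[sample] = 0
            continue
        chroms = np.array([r.chrom for r in records], dtype=object)
        pos = np.array([r.pos for r in records], dtype=np.int64)
        per_sample[sample] = int(merged.contains(chroms, pos).sum())
    total = sum(per_sample.values())
    census = None
    if reference is not None:
        seqs = as_seq_dict(reference)
        census = 0
        for chrom, sub in merged.frame.groupby("chrom"):
            if chrom not in seqs:
                raise KeyError(f"chromosome {chrom!r} absent from reference")
            seq = seqs[chrom]
            for s, e in zip(sub["start"], sub["end"]):
                piece = seq[s - 1: e].upper()
                if base_subset is None:
                    census += len(piece)
                else:
                    census += sum(piece.count(b) for b in base_subset.upper())
    return total, per_sample, census


def distance_to_feature(callset: Callset, midpoints: pd.DataFrame) -> Callset:
    """Annotate signed distance to the nearest feature midpoint (in place).

    Distance is ``pos - midpoint``; ties (equidistant midpoints) resolve
    toward the smaller-coordinate midpoint.  Records on contigs with no
    midpoint get ``dist_tfbs = None`` and a warning.
    """
    mids_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy(dtype=np.int64))
        for chrom, sub in midpoints.groupby("chrom")
    }
    missing = set()
    for records in callset.values():
        for r in records:
            mids = mids_by_chrom.get(r.chrom)
            if mids is None or len(mids) == 0:
                missing.add(r.chrom)
                r.dist_tfbs = None
                continue
            i = np.searchsorted(mids, r.pos)
            best = None
            for j in (i - 1, i):
                if 0 <= j < len(mids):
                    d = r.pos - int(mids[j])
                    # strictly smaller |d| wins; ties go to the earlier
                    # (smaller-coordinate) midpoint, i.e. the first candidate
                    if best is None or abs(d) < abs(best):
                        best = d
            r.dist_tfbs = best
    if missing:
        warnings.warn(f"no midpoints on contigs {sorted(missing)}; distances undefined")
    return callset
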