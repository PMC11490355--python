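"""Synthetic somatic-mosaicism cohort generator.

Builds a toy single-contig genome, regulatory annotation tracks, a
case/control covariate table, and per-sample somatic SNV call sets with
planted mutational processes:

- per-sample mutation counts drawn from a negative binomial (overdispersed,
  as in real deep-WGS mosaic call sets);
- uniform background placement with a case-specific multiplicative
  enrichment of T>G and/or CpG>GpG substitutions within a halfwidth of
  active-TFBS midpoints;
- rare hotspot sites that fire independently per case, producing identical
  variants across samples (same-variant-same-site recurrence);
- VAFs from a truncated Beta and read support binomial at a fixed depth.

Every emitted variant carries its generating class so downstream recovery
tests can be scored against the ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._contexts import encode_seq
from .intervals import IntervalTrack, promoter_track
from .reference import write_fasta
from .variants import Callset, VariantRecord, write_callset_tsv

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real cohort's scale: 60 cases / 25 controls,
    ~35 somatic SNVs per sample with variance roughly twice the mean,
    sequencing depth 239, VAFs in ~(0.009, 0.40].
    """

    genome_length: int = 5_000_000
    gc_fraction: float = 0.42
    n_tfbs: int = 400
    tfbs_width: int = 20
    dhs_score_shape: float = 2.0
    n_tss: int = 120
    n_cds: int = 150
    cds_width: int = 1_000
    n_case: int = 60
    n_control: int = 25
    nb_mean: float = 35.0
    nb_dispersion: float = 10.0  # NB size k; variance = mu + mu^2/k
    vaf_alpha: float = 2.2
    vaf_beta: float = 30.0
    depth: int = 239
    enrich_tg: float = 1.0
    enrich_cpg_transversion: float = 1.0
    enrich_halfwidth: int = 100
    active_quantile: float = 0.90
    n_hotspots: int = 0
    hotspot_hit_prob: float = 0.0
    contaminate_germline: float = 0.0  # per-sample expected count of VAF~0.5 spikes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")
        if not (0 < self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in (0, 1]")
        if min(self.n_tfbs, self.n_tss, self.n_case, self.n_control,
               self.n_hotspots) < 0:
            raise ValueError("counts must be non-negative")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be positive")
        if self.enrich_tg < 1 or self.enrich_cpg_transversion < 1:
            raise ValueError("enrichment multipliers must be >= 1")
        if not (0 <= self.hotspot_hit_prob <= 1):
            raise ValueError("hotspot_hit_prob must be a probability")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort for recovery tests."""

    seed: int
    config: SimulationConfig
    sample_counts: dict[str, dict[str, int]]  # sample -> {class: count}
    hotspot_sites: list[tuple[str, int, str, str]]
    active_midpoints: list[int]
    enrich_tg: float
    enrich_cpg_transversion: float
    hotspot_hit_prob: float

    @property
    def lambda1_true(self) -> float:
        """Expected per-hotspot-site mutation count across the case cohort."""
        return self.config.n_case * self.hotspot_hit_prob

    def class_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for counts in self.sample_counts.values():
            for k, v in counts.items():
                totals[k] = totals.get(k, 0) + v
        return totals

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["config"] = dataclasses.asdict(self.config)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["config"] = SimulationConfig(**payload["config"])
        payload["hotspot_sites"] = [tuple(h) for h in payload["hotspot_sites"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _streams(seed: int):
    root = np.random.SeedSequence(seed)
    ref_ss, track_ss, cohort_ss, cov_ss = root.spawn(4)
    return ref_ss, track_ss, cohort_ss, cov_ss


def generate_reference(config: SimulationConfig, contig: str = "chr1") -> dict[str, str]:
    """I.i.d. random genome with P(G) + P(C) = ``gc_fraction``."""
    ref_ss, _, _, _ = _streams(config.seed)
    rng = np.random.default_rng(ref_ss)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=config.genome_length, p=p)
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")
    return {contig: seq}


def generate_tracks(
    reference: dict[str, str], config: SimulationConfig
) -> dict[str, IntervalTrack]:
    """Disjoint TFBS with gamma DHS scores, promoters, and CDS intervals.

    TFBS are placed one per equal-width slot (random offset within the
    slot), which guarantees non-overlap; each TFBS receives a DHS intensity
    drawn from Gamma(shape=``dhs_score_shape``, scale=1).  The DHS track
    shares the TFBS intervals (scores attached there).  Promoters are the
    2500 bp upstream of each TSS.
    """
    (contig, seq), = reference.items()
    L = len(seq)
    _, track_ss, _, _ = _streams(config.seed)
    rng = np.random.default_rng(track_ss)

    w = config.tfbs_width
    slot = L // config.n_tfbs
    if slot <= w:
        raise ValueError("cannot fit requested TFBS without overlap")
    offsets = rng.integers(0, slot - w, size=config.n_tfbs)
    starts = np.arange(config.n_tfbs) * slot + offsets + 1  # 1-based
    ends = np.minimum(starts + w - 1, L)
    scores = rng.gamma(config.dhs_score_shape, 1.0, size=config.n_tfbs)

    tfbs = IntervalTrack(
        "tfbs",
        pd.DataFrame({"chrom": contig, "start": starts, "end": ends}),
        provenance="synthetic",
    )
    dhs = IntervalTrack(
        "dhs",
        pd.DataFrame({"chrom": contig, "start": starts, "end": ends, "score": scores}),
        provenance="synthetic",
    )

    tss_pos = np.sort(rng.integers(3000, L - 3000, size=config.n_tss))
    promoters = promoter_track(
        pd.DataFrame({"chrom": contig, "pos": tss_pos}), genome_length=L)

    cds_starts = np.sort(rng.integers(1, L - config.cds_width, size=config.n_cds))
    cds = IntervalTrack(
        "cds",
        pd.DataFrame({
            "chrom": contig, "start": cds_starts,
            "end": np.minimum(cds_starts + config.cds_width - 1, L),
        }),
        provenance="synthetic",
    )
    return {"tfbs": tfbs, "dhs": dhs, "promoters": promoters, "cds": cds}


def _active_midpoints(tracks: dict[str, IntervalTrack], config: SimulationConfig) -> np.ndarray:
    scores = tracks["dhs"].scores
    thr = np.quantile(scores, config.active_quantile)
    keep = scores >= thr
    mids = tracks["tfbs"].midpoints()["pos"].to_numpy()
    return np.sort(mids[keep])


def simulate_callset(
    reference: dict[str, str],
    tracks: dict[str, IntervalTrack],
    config: SimulationConfig,
) -> tuple[Callset, CohortTruth]:
    """Per-sample somatic SNV call sets with planted processes.

    Mutation placement is a three-component mixture per case sample:
    uniform background over interior (site, alt) pairs, an extra
    T>G-at-active-TFBS component with weight ``(enrich_tg - 1)`` per
    eligible site, and an extra CpG>GpG component likewise — so the per-site
    rate of the targeted class inside the enriched windows is exactly the
    configured fold times background.  Controls place uniformly.  Hotspot
    sites fire independently per case with ``hotspot_hit_prob`` and always
    emit the same T>G variant.
    """
    (contig, seq), = reference.items()
    L = len(seq)
    codes = encode_seq(seq)
    _, _, cohort_ss, _ = _streams(config.seed)
    master = np.random.default_rng(cohort_ss.spawn(1)[0])

    has_enrichment = config.enrich_tg > 1 or config.enrich_cpg_transversion > 1
    mids = _active_midpoints(tracks, config)
    if has_enrichment and mids.size == 0:
        raise ValueError("enrichment requested but no active TFBS exist")

    interior = np.zeros(L, dtype=bool)
    interior[1:-1] = True

    near = np.zeros(L, dtype=bool)
    for m in mids:
        near[max(m - 1 - config.enrich_halfwidth, 0): m + config.enrich_halfwidth] = True
    near &= interior

    is_t_or_a = (codes == 0) | (codes == 3)
    is_c = codes == 1
    is_g = codes == 2
    cpg = np.zeros(L, dtype=bool)
    cpg[:-1] |= is_c[:-1] & is_g[1:]   # C of CpG on forward strand
    cpg[1:] |= is_g[1:] & is_c[:-1]    # paired G, CpG on reverse strand
    cpg &= interior

    elig_tg = np.flatnonzero(near & is_t_or_a)
    elig_cpg = np.flatnonzero(near & cpg)
    interior_idx_n = L - 2

    w_bg = 3.0 * interior_idx_n
    w_tg = (config.enrich_tg - 1.0) * elig_tg.size
    w_cpg = (config.enrich_cpg_transversion - 1.0) * elig_cpg.size

    # hotspot sites: interior T/A positions, drawn once for the cohort
    hot_sites: list[tuple[str, int, str, str]] = []
    if config.n_hotspots > 0:
        ta_idx = np.flatnonzero(interior & is_t_or_a)
        chosen = master.choice(ta_idx, size=config.n_hotspots, replace=False)
        for i in np.sort(chosen):
            ref_b = "ACGT"[codes[i]]
            alt_b = "G" if ref_b == "T" else "C"  # T>G on the pyrimidine strand
            hot_sites.append((contig, int(i) + 1, ref_b, alt_b))

    sample_ids = [f"case_{i:03d}" for i in range(config.n_case)] + \
                 [f"ctrl_{i:03d}" for i in range(config.n_control)]
    is_case = [True] * config.n_case + [False] * config.n_control
    sample_streams = cohort_ss.spawn(len(sample_ids) + 1)[1:]

    callset: Callset = {}
    sample_counts: dict[str, dict[str, int]] = {}
    p_nb = config.nb_dispersion / (config.nb_dispersion + config.nb_mean)

    for sid, case, ss in zip(sample_ids, is_case, sample_streams):
        rng = np.random.default_rng(ss)
        n = int(rng.negative_binomial(config.nb_dispersion, p_nb))
        counts = {"background": 0, "tfbs_tg": 0, "tfbs_cpg": 0,
                  "hotspot": 0, "germline_contam": 0}
        records: list[VariantRecord] = []
        taken: set[int] = set()

        weights = np.array([w_bg, w_tg if case else 0.0, w_cpg if case else 0.0])
        probs = weights / weights.sum()
        comps = rng.choice(3, size=n, p=probs)
        for comp in comps:
            for _ in range(100):  # resample same-site collisions within a sample
                if comp == 0:
                    i = int(rng.integers(1, L - 1))
                    ref_b = "ACGT"[codes[i]]
                    alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
                    origin = "background"
                elif comp == 1:
                    i = int(elig_tg[rng.integers(elig_tg.size)])
                    ref_b = "ACGT"[codes[i]]
                    alt_b = "G" if ref_b == "T" else "C"
                    origin = "tfbs_tg"
                else:
                    i = int(elig_cpg[rng.integers(elig_cpg.size)])
                    ref_b = "ACGT"[codes[i]]
                    alt_b = "G" if ref_b == "C" else "C"
                    origin = "tfbs_cpg"
                if i not in taken:
                    break
            taken.add(i)
            records.append(_make_record(sid, contig, i + 1, ref_b, str(alt_b),
                                        origin, rng, config))
            counts[origin] += 1

        if case:
            for site in hot_sites:
                if rng.random() < config.hotspot_hit_prob:
                    _, pos, ref_b, alt_b = site
                    if (pos - 1) in taken:
                        continue
                    taken.add(pos - 1)
                    records.append(_make_record(sid, contig, pos, ref_b, alt_b,
                                                "hotspot", rng, config))
                    counts["hotspot"] += 1

        if config.contaminate_germline > 0:
            n_germ = rng.poisson(config.contaminate_germline)
            for _ in range(n_germ):
                i = int(rng.integers(1, L - 1))
                if i in taken:
                    continue
                taken.add(i)
                ref_b = "ACGT"[codes[i]]
                alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
                vaf = float(np.clip(rng.normal(0.5, 0.02), 0.35, 0.65))
                alt_reads = max(int(rng.binomial(config.depth, vaf)), 1)
                records.append(VariantRecord(
                    sample_id=sid, chrom=contig, pos=i + 1, ref=ref_b,
                    alt=str(alt_b), alt_reads=alt_reads, total_reads=config.depth,
                    origin="germline_contam"))
                counts["germline_contam"] += 1

        records.sort(key=lambda r: r.pos)
        callset[sid] = records
        sample_counts[sid] = counts

    truth = CohortTruth(
        seed=config.seed, config=config, sample_counts=sample_counts,
        hotspot_sites=hot_sites, active_midpoints=[int(m) for m in mids],
        enrich_tg=config.enrich_tg,
        enrich_cpg_transversion=config.enrich_cpg_transversion,
        hotspot_hit_prob=config.hotspot_hit_prob,
    )
    return callset, truth


def _make_record(sid, contig, pos, ref_b, alt_b, origin, rng, config) -> VariantRecord:
    # truncated Beta VAF in (0, 0.40]
    for _ in range(1000):
        vaf = rng.beta(config.vaf_alpha, config.vaf_beta)
        if 0 < vaf <= 0.40:
            break
    # read support consistent with the VAF; condition on being observed
    alt_reads = 0
    while alt_reads == 0:
        alt_reads = int(rng.binomial(config.depth, vaf))
    return VariantRecord(
        sample_id=sid, chrom=contig, pos=pos, ref=ref_b, alt=alt_b,
        alt_reads=alt_reads, total_reads=config.depth, origin=origin)


# ---------------------------------------------------------------------------
# Cohort IO
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=2,Type=Integer,Description="Ref and alt read counts">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##contig=<ID={contig},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_cohort(
    callset: Callset,
    truth: CohortTruth,
    reference: dict[str, str],
    tracks: dict[str, IntervalTrack],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA, BED tracks, per-sample VCFs, combined TSV, covariates, truth."""
    if not callset:
        raise ValueError("empty cohort")
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)

    paths: dict[str, Path] = {}
    (contig, seq), = reference.items()

    paths["reference"] = outdir / "reference.fa"
    write_fasta(reference, paths["reference"])

    for name, track in tracks.items():
        p = outdir / "tracks" / f"{name}.bed"
        track.to_bed(p)
        paths[f"track_{name}"] = p

    for sid, records in callset.items():
        p = outdir / "samples" / f"{sid}.vcf"
        with open(p, "w") as fh:
            fh.write(_VCF_HEADER.format(contig=contig, length=len(seq)))
            for r in records:
                info = (f"DP={r.total_reads};AD={r.total_reads - r.alt_reads},"
                        f"{r.alt_reads};VAF={r.vaf:.6g}")
                fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")
        paths[f"vcf_{sid}"] = p

    paths["callset"] = outdir / "callset.tsv"
    write_callset_tsv(callset, paths["callset"])

    paths["covariates"] = outdir / "covariates.tsv"
    covariates_table(truth.config).to_csv(paths["covariates"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths


def covariates_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample covariates (diagnosis, sex, coverage, pmi, age)."""
    _, _, _, cov_ss = _streams(config.seed)
    rng = np.random.default_rng(cov_ss)
    n = config.n_case + config.n_control
    sample_ids = [f"case_{i:03d}" for i in range(config.n_case)] + \
                 [f"ctrl_{i:03d}" for i in range(config.n_control)]
    return pd.DataFrame({
        "sample_id": sample_ids,
        "diagnosis": ["case"] * config.n_case + ["control"] * config.n_control,
        "sex": rng.choice(["M", "F"], size=n),
        "coverage": np.round(rng.normal(config.depth, 20, size=n), 1),
        "pmi": np.round(rng.gamma(4.0, 5.0, size=n), 1),
        "age": np.round(rng.normal(65, 12, size=n), 0).astype(int),
    })
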