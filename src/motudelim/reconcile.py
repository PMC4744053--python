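"""Reconciliation of MOTU partitions against morphospecies labels.

Each morphospecies is classified against a partition:

* ``consistent`` — all its specimens form exactly one MOTU containing no
  other species (singletons: ``singleton_consistent`` when their MOTU is
  private);
* ``split`` — its specimens fall into two or more MOTUs, each pure;
* ``shared`` — some MOTU containing its specimens also contains another
  species (``singleton_shared`` for singletons). Sharing is the stronger
  conflict, so a species both split and sharing is classified shared.

Cryptic-candidate flags mark species whose maximum intraspecific distance
exceeds a cutoff (default 5%); zone flags mark the MOTUs that exist at the
lower edge of the 2.5-3.5% integrative-taxonomy zone but merge at its
upper edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from motudelim.abgd import AbgdConfig, abgd_partition
from motudelim.barcode_io import BarcodeDataset
from motudelim.distances import (
    DistanceMatrix,
    RankSummary,
    SpeciesPairStats,
    distance_matrix,
    low_divergence_pairs,
    max_intraspecific,
    rank_summaries,
)
from motudelim.motu_cluster import MotuPartition, SweepCurve, cluster_at, sweep
from motudelim.ptp import ptp_delimit
from motudelim.trees import midpoint_root, nj_tree, write_newick

__all__ = [
    "CaseClassification",
    "CrypticFlag",
    "ZoneFlag",
    "ReconciliationReport",
    "classify",
    "flag_cryptic",
    "zone_diff",
    "run_pipeline",
    "PipelineConfig",
]

logger = logging.getLogger("motudelim")


@dataclass(frozen=True)
class CaseClassification:
    morphospecies: str
    n_specimens: int
    n_motus: int
    status: str  # consistent | split | shared | singleton_consistent | singleton_shared
    partner_species: tuple[str, ...] = ()


@dataclass(frozen=True)
class CrypticFlag:
    morphospecies: str
    max_intra: float  # percent
    threshold_used: float  # percent


@dataclass(frozen=True)
class ZoneFlag:
    motu_id: str
    species: tuple[str, ...]
    reason: str = "appears between 2.5% and 3.5% thresholds"


@dataclass
class ReconciliationReport:
    """Aggregated output of the full delimitation pipeline."""

    classifications: list[CaseClassification]
    cryptic_flags: list[CrypticFlag]
    zone_flags: list[ZoneFlag]
    low_divergence: list[SpeciesPairStats]
    rank_summaries: list[RankSummary]
    motu_counts: dict[str, int]
    partitions: dict[str, MotuPartition] = field(default_factory=dict)
    sweep_curve: SweepCurve | None = None
    newick: str | None = None

    def n_by_status(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classifications:
            out[c.status] = out.get(c.status, 0) + 1
        return out

    def n_consistent(self) -> int:
        by = self.n_by_status()
        return by.get("consistent", 0) + by.get("singleton_consistent", 0)


def classify(partition: MotuPartition, ds: BarcodeDataset) -> list[CaseClassification]:
    """Classify every morphospecies against a MOTU partition."""
    ids = set(ds.sample_ids)
    if set(partition.assignment) != ids:
        raise ValueError("partition does not cover the dataset's sample ids")
    species_of = {s: ds.species_of(s) for s in ids}
    motu_members = partition.motus()
    motu_species = {m: {species_of[s] for s in mem} for m, mem in motu_members.items()}
    by_species: dict[str, list[str]] = {}
    for s in ds.sample_ids:
        by_species.setdefault(species_of[s], []).append(s)

    out: list[CaseClassification] = []
    for sp, members in by_species.items():
        motus = sorted({partition.assignment[s] for s in members})
        partners = tuple(sorted({o for m in motus for o in motu_species[m] if o != sp}))
        singleton = len(members) == 1
        if partners:
            status = "singleton_shared" if singleton else "shared"
        elif singleton:
            status = "singleton_consistent"
        elif len(motus) > 1:
            status = "split"
        else:
            status = "consistent"
        out.append(
            CaseClassification(morphospecies=sp, n_specimens=len(members),
                               n_motus=len(motus), status=status,
                               partner_species=partners)
        )
    key = {sp: (ds.record_of(m[0]).tribe, ds.record_of(m[0]).genus, sp)
           for sp, m in by_species.items()}
    out.sort(key=lambda c: key[c.morphospecies])
    return out


def flag_cryptic(max_intra: dict[str, float], cutoff: float = 5.0) -> list[CrypticFlag]:
    """Species whose maximum intraspecific distance (percent) exceeds ``cutoff``."""
    flags = [CrypticFlag(sp, v, cutoff) for sp, v in max_intra.items() if v > cutoff]
    flags.sort(key=lambda f: -f.max_intra)
    return flags


def zone_diff(
    p_low: MotuPartition, p_high: MotuPartition, ds: BarcodeDataset
) -> list[ZoneFlag]:
    """MOTUs of the finer partition that merge away in the coarser one.

    The number of flags equals ``n_motus(p_low) - n_motus(p_high)``: for
    each group of low-threshold MOTUs that fuse into one high-threshold
    MOTU, all but the first are flagged (the excess MOTUs created by
    lowering the threshold).
    """
    if set(p_low.assignment) != set(p_high.assignment):
        raise ValueError("partitions cover different sample sets")
    fused: dict[str, list[str]] = {}
    for motu_lo, members in p_low.motus().items():
        his = {p_high.assignment[s] for s in members}
        assert len(his) == 1, "low-threshold partition must refine the high-threshold one"
        fused.setdefault(next(iter(his)), []).append(motu_lo)
    flags: list[ZoneFlag] = []
    lo_members = p_low.motus()
    for hi, lows in sorted(fused.items()):
        if len(lows) < 2:
            continue
        for motu_lo in lows[1:]:
            species = tuple(sorted({ds.species_of(s) for s in lo_members[motu_lo]}))
            flags.append(ZoneFlag(motu_id=motu_lo, species=species))
    return flags


@dataclass
class PipelineConfig:
    model: str = "k2p"
    threshold: float = 3.6  # percent
    zone: tuple[float, float] = (2.5, 3.5)  # percent
    cryptic_cutoff: float = 5.0  # percent
    low_divergence_cutoff: float = 4.0  # percent
    sweep_grid: tuple[float, float, float] = (0.0, 8.0, 0.1)  # percent
    abgd: AbgdConfig = field(default_factory=AbgdConfig)
    run_abgd: bool = True
    run_ptp: bool = True


def run_pipeline(
    ds: BarcodeDataset,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> ReconciliationReport:
    """Run the full delimitation pipeline and (optionally) write the report.

    Stages: distance matrix -> rank summaries -> threshold sweep ->
    furthest-neighbor partition at the headline threshold -> ABGD over the
    prior grid -> midpoint-rooted NJ tree + PTP -> reconciliation and flags.
    """
    cfg = config or PipelineConfig()
    logger.info("pipeline start: %d sequences, model=%s", len(ds), cfg.model)

    dm = distance_matrix(ds, model=cfg.model)
    summaries = rank_summaries(dm, ds)
    logger.info("distances: %s", {s.stratum: s.n_comparisons for s in summaries})
    mi = max_intraspecific(dm, ds)
    pairs = low_divergence_pairs(dm, ds, cutoff=cfg.low_divergence_cutoff)

    curve = sweep(dm, *cfg.sweep_grid)
    headline = cluster_at(dm, cfg.threshold / 100.0)
    p_low = cluster_at(dm, cfg.zone[0] / 100.0)
    p_high = cluster_at(dm, cfg.zone[1] / 100.0)
    logger.info("MOTUs: %d at %.2f%%, %d at %.2f%%, %d at %.2f%%",
                headline.n_motus, cfg.threshold, p_low.n_motus, cfg.zone[0],
                p_high.n_motus, cfg.zone[1])

    motu_counts = {
        f"furthest_neighbor@{cfg.threshold}%": headline.n_motus,
        f"furthest_neighbor@{cfg.zone[0]}%": p_low.n_motus,
        f"furthest_neighbor@{cfg.zone[1]}%": p_high.n_motus,
    }
    partitions = {"headline": headline, "zone_low": p_low, "zone_high": p_high}

    if cfg.run_abgd:
        abgd_results = abgd_partition(dm, cfg.abgd)
        grid = [r.prior_P for r in abgd_results]
        mid = min(range(len(grid)), key=lambda i: abs(grid[i] - 0.0129))
        motu_counts[f"abgd@P={grid[mid]:.4f}"] = abgd_results[mid].partition.n_motus
        partitions["abgd"] = abgd_results[mid].partition
        logger.info("ABGD: %s",
                    [(round(r.prior_P, 4), r.partition.n_motus) for r in abgd_results])

    newick = None
    if cfg.run_ptp and len(ds) >= 3:
        tree = midpoint_root(nj_tree(dm))
        newick = write_newick(tree)
        ptp_part, ptp_model = ptp_delimit(tree)
        motu_counts["ptp"] = ptp_part.n_motus
        partitions["ptp"] = ptp_part
        logger.info("PTP: %d species, logL=%.2f (null %.2f)", ptp_part.n_motus,
                    ptp_model.log_likelihood, ptp_model.null_log_likelihood)

    report = ReconciliationReport(
        classifications=classify(headline, ds),
        cryptic_flags=flag_cryptic(mi, cutoff=cfg.cryptic_cutoff),
        zone_flags=zone_diff(p_low, p_high, ds),
        low_divergence=pairs,
        rank_summaries=summaries,
        motu_counts=motu_counts,
        partitions=partitions,
        sweep_curve=curve,
        newick=newick,
    )
    if out_dir is not None:
        _write_report(report, ds, dm, Path(out_dir))
    logger.info("pipeline done: %d/%d morphospecies consistent",
                report.n_consistent(), len(report.classifications))
    return report


def _write_report(
    report: ReconciliationReport, ds: BarcodeDataset, dm: DistanceMatrix, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in report.rank_summaries]).to_csv(
        out / "rank_summaries.tsv", sep="\t", index=False, float_format="%.2f")
    pd.DataFrame([vars(c) for c in report.classifications]).to_csv(
        out / "classifications.tsv", sep="\t", index=False)
    pd.DataFrame([vars(f) for f in report.cryptic_flags]).to_csv(
        out / "cryptic_flags.tsv", sep="\t", index=False, float_format="%.2f")
    pd.DataFrame([vars(z) for z in report.zone_flags]).to_csv(
        out / "zone_flags.tsv", sep="\t", index=False)
    pd.DataFrame([vars(p) for p in report.low_divergence]).to_csv(
        out / "low_divergence_pairs.tsv", sep="\t", index=False, float_format="%.2f")
    for name, part in report.partitions.items():
        pd.DataFrame(sorted(part.assignment.items()),
                     columns=["sample_id", "motu_id"]).to_csv(
            out / f"assignment_{name}.tsv", sep="\t", index=False)
    if report.sweep_curve is not None:
        pd.DataFrame({"threshold_pct": report.sweep_curve.grid,
                      "n_motus": report.sweep_curve.counts}).to_csv(
            out / "sweep.tsv", sep="\t", index=False)
    if report.newick is not None:
        (out / "nj_midpoint.nwk").write_text(report.newick)
    dm.write_square(out / "distance_matrix.tsv")
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"sequences: {len(ds)}\n")
        fh.write(f"morphospecies: {len(report.classifications)}\n")
        fh.write(f"status counts: {report.n_by_status()}\n")
        fh.write(f"MOTU counts: {report.motu_counts}\n")
        fh.write(f"cryptic flags: {[f.morphospecies for f in report.cryptic_flags]}\n")
        fh.write(f"zone excess MOTUs: {len(report.zone_flags)}\n")
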