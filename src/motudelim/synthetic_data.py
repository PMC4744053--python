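"""Synthetic barcode datasets with controlled divergence structure.

Sequences evolve along an explicit species genealogy under the continuous-
time Kimura two-parameter (K80) substitution model, with branch lengths in
expected substitutions per site so that the K2P distance estimator is
calibrated to the generating branch lengths. The genealogy is a fixed
hierarchy: one global root, tribe ancestors, genus ancestors, species
ancestors, and a star of tips per species (equal branches of half the
target intraspecific divergence, which makes expected pairwise divergences
analytic):

    tip-tip within species            ~ target_intra
    tip-tip between congeneric species ~ target_inter_congeneric
    tip-tip between genera / tribes    ~ target_intergeneric / target_intertribal

Ancestral sequences are uniform over codons that are stop-free under the
invertebrate mitochondrial code; any stop codon created by simulated
substitutions is repaired (middle base set to C) so that clean datasets
always pass Numt screening. Optional Numt corruption replaces one
mid-sequence codon with TAA in a deterministic fraction of sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from motudelim.barcode_io import AlignedBarcode, BarcodeDataset, SpecimenRecord

__all__ = ["SpeciesSpec", "SimConfig", "simulate_dataset", "simulate_tree_dataset",
           "study_shaped_config"]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code
# transition partner of code i (A<->G, C<->T): 0<->2, 1<->3
_TS_PARTNER = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated morphospecies."""

    label: str
    n_specimens: int
    target_intra: float  # expected pairwise K2P within the species (proportion)
    genus: str
    tribe: str

    def __post_init__(self) -> None:
        if not (0 <= self.target_intra < 0.2):
            raise ValueError(f"target_intra must be in [0, 0.2), got {self.target_intra}")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")


@dataclass
class SimConfig:
    """Full simulation configuration.

    ``ambiguous_zone_fraction`` is the fraction of multi-species genera whose
    congeneric divergence target is drawn in the 2.5-3.5% "integrative
    taxonomy" zone instead of ``target_inter_congeneric``.
    """

    species: list[SpeciesSpec]
    target_inter_congeneric: float = 0.115
    kappa: float = 4.0  # transition/transversion rate ratio
    seq_length: int = 658
    seed: int = 0
    numt_fraction: float = 0.0
    frame_offset: int = 1
    target_intergeneric: float | None = None  # default: 1.7x congeneric, capped
    target_intertribal: float | None = None  # default: intergeneric + 0.02
    ambiguous_zone_fraction: float = 0.0
    inter_spread: float = 0.0  # lognormal sigma of per-genus congeneric divergence

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("no species specified")
        max_intra = max(s.target_intra for s in self.species)
        if self.target_inter_congeneric <= max_intra:
            raise ValueError(
                f"target_inter_congeneric ({self.target_inter_congeneric}) must exceed "
                f"the largest target_intra ({max_intra})"
            )
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.seq_length < 6:
            raise ValueError("seq_length must be a positive integer >= 6")
        if self.target_intergeneric is None:
            self.target_intergeneric = min(1.7 * self.target_inter_congeneric + 0.02, 0.30)
        if self.target_intertribal is None:
            self.target_intertribal = min(self.target_intergeneric + 0.02, 0.33)


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-type transversion prob) after branch length t.

    K80 rates normalized to one expected substitution per unit length:
    alpha = kappa / (kappa + 2), beta = 1 / (kappa + 2).
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def _evolve(seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along a branch of length t substitutions/site."""
    if t <= 0:
        return seq.copy()
    p_ts, p_tv = _k80_probs(t, kappa)
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = _TS_PARTNER[seq[ts]]
    # transversion partners: purines (A,G) -> {C,T}; pyrimidines (C,T) -> {A,G}
    out[tv1] = np.where((seq[tv1] & 1) == 0, 1, 0)
    out[tv2] = np.where((seq[tv2] & 1) == 0, 3, 2)
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


def _random_coding_root(length: int, frame_offset: int, rng: np.random.Generator) -> np.ndarray:
    seq = rng.integers(0, 4, size=length)
    _repair_stops(seq, frame_offset)
    return seq


def _repair_stops(seq: np.ndarray, frame_offset: int) -> None:
    """Replace the middle base of any in-frame TAA/TAG codon with C, in place."""
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = _BASES[seq[i]] + _BASES[seq[i + 1]] + _BASES[seq[i + 2]]
        if codon in _STOPS:
            seq[i + 1] = 1  # C


def simulate_tree_dataset(cfg: SimConfig) -> tuple[BarcodeDataset, dendropy.Tree, dict[str, str]]:
    """Simulate a dataset plus its true genealogy and species assignment.

    Returns ``(dataset, rooted_tree, truth)`` where ``truth`` maps sample id
    to the generating species label. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L, kappa, off = cfg.seq_length, cfg.kappa, cfg.frame_offset

    tribes: dict[str, dict[str, list[SpeciesSpec]]] = {}
    for sp in cfg.species:
        tribes.setdefault(sp.tribe, {}).setdefault(sp.genus, []).append(sp)

    # per-genus congeneric divergence target (ambiguous-zone genera drawn low)
    inter_of: dict[str, float] = {}
    for tribe in sorted(tribes):
        for genus in sorted(tribes[tribe]):
            specs = tribes[tribe][genus]
            if len(specs) > 1 and rng.random() < cfg.ambiguous_zone_fraction:
                inter_of[genus] = rng.uniform(0.025, 0.035)
            elif cfg.inter_spread > 0:
                # mean-preserving lognormal spread across genera
                draw = cfg.target_inter_congeneric * math.exp(
                    rng.normal(0.0, cfg.inter_spread) - cfg.inter_spread ** 2 / 2.0
                )
                inter_of[genus] = min(max(draw, 0.04), 0.27)
            else:
                inter_of[genus] = cfg.target_inter_congeneric
            max_intra = max(s.target_intra for s in specs)
            if inter_of[genus] <= max_intra:
                inter_of[genus] = max_intra + 0.01

    b_tribe = max((cfg.target_intertribal - cfg.target_intergeneric) / 2.0, 0.0)
    root_seq = _random_coding_root(L, off, rng)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True

    alignment: list[AlignedBarcode] = []
    records: list[SpecimenRecord] = []
    truth: dict[str, str] = {}
    counter = 0

    for tribe in sorted(tribes):
        tribe_seq = _evolve(root_seq, b_tribe, kappa, rng)
        tribe_node = dendropy.Node()
        tribe_node.edge.length = b_tribe
        tree.seed_node.add_child(tribe_node)
        for genus in sorted(tribes[tribe]):
            inter = inter_of[genus]
            b_genus = max((cfg.target_intergeneric - inter) / 2.0, 0.0)
            genus_seq = _evolve(tribe_seq, b_genus, kappa, rng)
            genus_node = dendropy.Node()
            genus_node.edge.length = b_genus
            tribe_node.add_child(genus_node)
            for sp in tribes[tribe][genus]:
                b_sp = max((inter - sp.target_intra) / 2.0, 0.0)
                sp_seq = _evolve(genus_seq, b_sp, kappa, rng)
                sp_node = dendropy.Node()
                sp_node.edge.length = b_sp
                genus_node.add_child(sp_node)
                for k in range(sp.n_specimens):
                    counter += 1
                    sid = f"s{counter:04d}"
                    tip_seq = _evolve(sp_seq, sp.target_intra / 2.0, kappa, rng)
                    _repair_stops(tip_seq, off)
                    taxon = taxa.new_taxon(sid)
                    tip = dendropy.Node(taxon=taxon)
                    tip.edge.length = sp.target_intra / 2.0
                    sp_node.add_child(tip)
                    alignment.append(AlignedBarcode(sid, _decode(tip_seq)))
                    records.append(
                        SpecimenRecord(sample_id=sid, morphospecies=sp.label,
                                       genus=sp.genus, tribe=sp.tribe,
                                       country="synthetic", source="field")
                    )
                    truth[sid] = sp.label

    if cfg.numt_fraction > 0:
        n_corrupt = round(cfg.numt_fraction * len(alignment))
        victims = rng.choice(len(alignment), size=n_corrupt, replace=False)
        codon_start = off + 3 * (((len(alignment[0].sequence) - off) // 3) // 2)
        for v in sorted(victims):
            ab = alignment[v]
            s = ab.sequence
            alignment[v] = AlignedBarcode(ab.sample_id,
                                          s[:codon_start] + "TAA" + s[codon_start + 3:])

    ds = BarcodeDataset(records=records, alignment=alignment, frame_offset=off)
    return ds, tree, truth


def simulate_dataset(cfg: SimConfig) -> BarcodeDataset:
    """Simulate a barcode dataset (see :func:`simulate_tree_dataset`)."""
    ds, _, _ = simulate_tree_dataset(cfg)
    return ds


def study_shaped_config(
    seed: int = 0,
    n_species: int = 84,
    n_singletons: int = 38,
    n_sequences: int = 421,
    n_genera: int = 36,
    tribe_sizes: tuple[int, ...] = (4, 18, 14),
    numt_fraction: float = 0.0,
    ambiguous_zone_fraction: float = 0.10,
) -> SimConfig:
    """A configuration shaped like a subfamily-scale COI reference library.

    Defaults emulate a survey of 421 sequences from 84 morphospecies (38
    singletons, 46 multi-specimen species) in 36 genera and 3 tribes, with
    intraspecific divergence mostly below 2%, a small tail of deeply
    divergent (cryptic-like) species, and congeneric divergence centred
    near 11-12%, a small fraction of genera falling in the 2.5-3.5%
    ambiguous zone.
    """
    assert sum(tribe_sizes) == n_genera
    rng = np.random.default_rng(seed)
    tribe_names = [f"Tribe{chr(65 + i)}" for i in range(len(tribe_sizes))]
    genus_tribe: list[tuple[str, str]] = []
    g = 0
    for tname, size in zip(tribe_names, tribe_sizes):
        for _ in range(size):
            g += 1
            genus_tribe.append((f"Genus{g:02d}", tname))

    # distribute species over genera: every genus gets one, the rest at random
    species_per_genus = np.ones(n_genera, dtype=int)
    extra = rng.choice(n_genera, size=n_species - n_genera, replace=True)
    for e in extra:
        species_per_genus[e] += 1

    # specimen counts: singletons plus a right-skewed multi-specimen tail
    n_multi = n_species - n_singletons
    counts = np.minimum(rng.geometric(0.18, size=n_multi) + 1, 45)
    target = n_sequences - n_singletons
    while counts.sum() != target:  # nudge toward the exact sequence total
        i = int(rng.integers(n_multi))
        if counts.sum() > target and counts[i] > 2:
            counts[i] -= 1
        elif counts.sum() < target:
            counts[i] += 1
    sampling = np.array([1] * n_singletons + list(counts))
    rng.shuffle(sampling)

    # intraspecific targets: mostly < 2%, some moderate, a cryptic-like tail;
    # heavily sampled species are kept shallow, as in real reference libraries
    intras = []
    for k in range(n_species):
        u = rng.random()
        deep_sampling = sampling[k] >= 10
        if u < (0.85 if deep_sampling else 0.70):
            intras.append(rng.uniform(0.0, 0.012))
        elif u < 0.94 or deep_sampling:
            intras.append(rng.uniform(0.012, 0.04))
        else:
            intras.append(rng.uniform(0.055, 0.105))

    species: list[SpeciesSpec] = []
    si = 0
    for (genus, tribe), k in zip(genus_tribe, species_per_genus):
        for _ in range(k):
            si += 1
            species.append(
                SpeciesSpec(
                    label=f"{genus}_sp{si:03d}",
                    n_specimens=int(sampling[si - 1]),
                    target_intra=float(intras[si - 1]),
                    genus=genus,
                    tribe=tribe,
                )
            )
    return SimConfig(
        species=species,
        target_inter_congeneric=0.115,
        kappa=4.0,
        seq_length=658,
        seed=seed,
        numt_fraction=numt_fraction,
        ambiguous_zone_fraction=ambiguous_zone_fraction,
        inter_spread=0.35,
    )
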