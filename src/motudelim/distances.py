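"""Pairwise genetic distances (p, JC69, K2P) and rank-stratified summaries.

Distances are computed with pairwise deletion: alignment columns where
either sequence carries a gap, an N, or any IUPAC ambiguity code are
excluded from that pair's comparison. With P and Q the transition
(A<->G, C<->T) and transversion mismatch proportions over the comparable
sites, and p = P + Q the raw mismatch proportion:

    p-distance   d = p
    JC69         d = -(3/4) ln(1 - (4/3) p)
    K2P          d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q))

Distances are stored as proportions; report helpers render percentages.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from motudelim.barcode_io import AlignedBarcode, BarcodeDataset

__all__ = [
    "DistanceMatrix",
    "RankSummary",
    "SpeciesPairStats",
    "pair_distance",
    "distance_matrix",
    "rank_summaries",
    "max_intraspecific",
    "low_divergence_pairs",
    "SaturationError",
    "encode_alignment",
    "STRATA",
]

MODELS = ("p", "jc69", "k2p")
STRATA = (
    "within_species",
    "within_genus_between_species",
    "within_tribe_between_genera",
    "between_tribes",
)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
# A=0, C=1, G=2, T=3: purines are even, pyrimidines odd, so a mismatch is a
# transition iff both codes share parity.


class SaturationError(ValueError):
    """Distance correction undefined: substitution saturation (log argument <= 0)."""


def encode_alignment(ds: BarcodeDataset) -> np.ndarray:
    """Encode sequences as an (n, L) uint8 matrix; 255 marks missing data."""
    arr = np.frombuffer(
        "".join(a.sequence for a in ds.alignment).encode("ascii"), dtype=np.uint8
    ).reshape(len(ds), ds.length)
    return _CODE[arr]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site bookkeeping."""

    ids: list[str]
    values: np.ndarray  # proportions
    model: str
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n) and self.comparable_sites.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id: str) -> int:
        if not hasattr(self, "_idx"):
            self._idx = {s: i for i, s in enumerate(self.ids)}
        return self._idx[sample_id]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def write_square(self, path: str | Path) -> None:
        """PHYLIP-style square tab-separated matrix at full precision."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{sid}\t{row}\n")

    def write_long(self, path: str | Path) -> None:
        """Long-format pair table: id_a, id_b, distance, comparable_sites."""
        rows = []
        for i, j in itertools.combinations(range(self.n), 2):
            rows.append((self.ids[i], self.ids[j], float(self.values[i, j]),
                         int(self.comparable_sites[i, j])))
        pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "comparable_sites"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class RankSummary:
    """Distance summary for one taxonomic stratum (percent units)."""

    stratum: str
    n_comparisons: int
    mean: float
    min: float
    max: float
    se: float


@dataclass(frozen=True)
class SpeciesPairStats:
    """Interspecific K2P range for one congeneric morphospecies pair (percent units)."""

    species_a: str
    species_b: str
    min: float
    max: float
    n_pairs: int


def _correct(P: float, Q: float, model: str, saturation_cap: float | None) -> float:
    p = P + Q
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - (4.0 / 3.0) * p
    elif model == "k2p":
        arg = (1.0 - 2.0 * P - Q) * math.sqrt(max(1.0 - 2.0 * Q, 0.0))
    else:
        raise ValueError(f"unknown model {model!r}")
    if arg <= 0.0:
        if saturation_cap is not None:
            return saturation_cap
        raise SaturationError(
            f"{model} distance undefined (P={P:.4f}, Q={Q:.4f}): saturated pair"
        )
    if model == "jc69":
        return -0.75 * math.log(arg) + 0.0  # +0.0 normalizes -0.0
    return -0.5 * math.log(arg) + 0.0


def pair_distance(
    x: AlignedBarcode,
    y: AlignedBarcode,
    model: str = "k2p",
    min_sites: int = 100,
    saturation_cap: float | None = None,
) -> tuple[float, int]:
    """Distance between two aligned barcodes under ``model``.

    Returns ``(distance, comparable_sites)``. Pairs with fewer than
    ``min_sites`` comparable positions raise a warning and return NaN.
    """
    if len(x.sequence) != len(y.sequence):
        raise ValueError("sequences differ in length; not an alignment")
    a = _CODE[np.frombuffer(x.sequence.encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(y.sequence.encode("ascii"), dtype=np.uint8)]
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n < min_sites:
        warnings.warn(
            f"pair ({x.sample_id}, {y.sample_id}) has only {n} comparable sites "
            f"(< {min_sites}); excluded", stacklevel=2,
        )
        return float("nan"), n
    aa, bb = a[mask], b[mask]
    diff = aa != bb
    ts = int((diff & ((aa & 1) == (bb & 1))).sum())
    tv = int(diff.sum()) - ts
    return _correct(ts / n, tv / n, model, saturation_cap), n


def distance_matrix(
    ds: BarcodeDataset,
    model: str = "k2p",
    min_sites: int = 100,
    saturation_cap: float | None = None,
) -> DistanceMatrix:
    """Full symmetric distance matrix for a dataset.

    Vectorized over alignment columns; pairwise deletion per pair.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    enc = encode_alignment(ds)
    n = len(ds)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, (enc[0] < 4).shape[0])
    valid = enc < 4
    parity = enc & 1
    for i in range(n - 1):
        mask = valid[i] & valid[i + 1 :]  # (n-i-1, L)
        comp = mask.sum(axis=1)
        diff = mask & (enc[i] != enc[i + 1 :])
        ts = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        tot = diff.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            cs = int(comp[k])
            if cs < min_sites:
                warnings.warn(
                    f"pair ({ds.sample_ids[i]}, {ds.sample_ids[j]}) has only {cs} "
                    f"comparable sites (< {min_sites}); excluded", stacklevel=2,
                )
                d = float("nan")
            else:
                d = _correct(ts[k] / cs, (tot[k] - ts[k]) / cs, model, saturation_cap)
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = cs
    return DistanceMatrix(ids=list(ds.sample_ids), values=values, model=model,
                          comparable_sites=sites)


def _stratum_of(ra, rb) -> str:
    if ra.morphospecies == rb.morphospecies:
        return "within_species"
    if ra.genus == rb.genus:
        return "within_genus_between_species"
    if ra.tribe == rb.tribe:
        return "within_tribe_between_genera"
    return "between_tribes"


def rank_summaries(dm: DistanceMatrix, ds: BarcodeDataset) -> list[RankSummary]:
    """Distance summaries stratified by taxonomic rank (Table-1 style).

    Every unordered sequence pair contributes to exactly one of the four
    strata. Values are rendered in percent. The standard error is the sample
    standard deviation of the stratum's distances over sqrt(n) — an analytic
    proxy, not a bootstrap.
    """
    recs = [ds.record_of(s) for s in dm.ids]
    buckets: dict[str, list[float]] = {s: [] for s in STRATA}
    for i, j in itertools.combinations(range(dm.n), 2):
        buckets[_stratum_of(recs[i], recs[j])].append(dm.values[i, j])
    out = []
    for stratum in STRATA:
        vals = np.asarray(buckets[stratum]) * 100.0
        if len(vals) == 0:
            out.append(RankSummary(stratum, 0, math.nan, math.nan, math.nan, math.nan))
            continue
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append(
            RankSummary(stratum, len(vals), float(vals.mean()), float(vals.min()),
                        float(vals.max()), se)
        )
    return out


def max_intraspecific(dm: DistanceMatrix, ds: BarcodeDataset) -> dict[str, float]:
    """Maximum intraspecific distance (percent) per multi-specimen morphospecies."""
    by_species: dict[str, list[int]] = {}
    for i, s in enumerate(dm.ids):
        by_species.setdefault(ds.species_of(s), []).append(i)
    out = {}
    for sp, idx in by_species.items():
        if len(idx) < 2:
            continue
        sub = dm.values[np.ix_(idx, idx)]
        out[sp] = float(sub.max() * 100.0)
    return out


def low_divergence_pairs(
    dm: DistanceMatrix, ds: BarcodeDataset, cutoff: float = 4.0
) -> list[SpeciesPairStats]:
    """Congeneric morphospecies pairs whose minimum interspecific distance is
    below ``cutoff`` percent, with the per-pair min/max range (Table-2 style)."""
    if cutoff <= 0:
        return []
    by_species: dict[str, list[int]] = {}
    genus_of: dict[str, str] = {}
    for i, s in enumerate(dm.ids):
        rec = ds.record_of(s)
        by_species.setdefault(rec.morphospecies, []).append(i)
        genus_of[rec.morphospecies] = rec.genus
    out = []
    for sa, sb in itertools.combinations(sorted(by_species), 2):
        if genus_of[sa] != genus_of[sb]:
            continue
        sub = dm.values[np.ix_(by_species[sa], by_species[sb])] * 100.0
        if float(sub.min()) < cutoff:
            out.append(
                SpeciesPairStats(sa, sb, float(sub.min()), float(sub.max()), sub.size)
            )
    out.sort(key=lambda s: s.min)
    return out
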