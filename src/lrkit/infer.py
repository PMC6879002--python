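"""Reconstruction of long molecules from barcoded read placements.

Real Linked-Read analyses never observe the input molecules directly; they
are inferred by grouping aligned read pairs that share a barcode and lie
near each other.  This module implements that reconstruction with the
standard filtering rules:

* a molecule is terminated when the distance between two consecutive
  same-barcode read pairs exceeds 50 kb (or the contig changes);
* reconstructed molecules need >= 2 read pairs and >= 2 kb of span;
* barcodes (partitions) retaining < 3 molecules are removed entirely.

On top of the reconstruction sit the library profile (fragment-length,
fragments-per-partition and per-fragment-depth statistics, plus estimates
of ``C_F``, ``C_R`` and ``N_F/P``) and barcode-aware subsampling to a
target ``C_R`` (per-molecule read thinning) or ``C_F`` (molecule dropping).

Placements come either from a coordinate-sorted SAM/BAM with ``BX`` barcode
tags or from the simulator's truth TSV sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, MutableMapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    EmptyInputError,
    FragmentLengthSummary,
    InvalidParameterError,
    genomic_bases_per_pair,
    summarize_lengths,
)

__all__ = [
    "ReadPlacement",
    "InferredFragment",
    "LibraryProfile",
    "measure_gap_distance",
    "infer_fragments",
    "profile_library",
    "subsample_reads",
    "subsample_fragments",
    "placements_from_truth",
    "placements_from_sam",
]

PLACEMENT_COLUMNS = ("read_id", "barcode", "contig", "leftmost", "rightmost")


@dataclass(frozen=True)
class ReadPlacement:
    """Outer span of one aligned read pair (0-based half-open)."""

    read_id: str
    barcode: str
    contig: str
    leftmost: int
    rightmost: int

    def __post_init__(self) -> None:
        if not self.leftmost < self.rightmost:
            raise InvalidParameterError("placement requires leftmost < rightmost")


@dataclass
class InferredFragment:
    """A reconstructed long molecule: one barcode's read chain."""

    barcode: str
    contig: str
    start: int
    end: int
    n_read_pairs: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def measure_gap_distance(p1: ReadPlacement, p2: ReadPlacement) -> float:
    """End-to-start distance between two same-barcode pair spans.

    ``p1`` must not start after ``p2``.  Overlapping or abutting spans have
    distance 0; placements on different contigs are infinitely far apart
    (forcing a molecule split).
    """
    if p1.barcode != p2.barcode:
        raise InvalidParameterError("placements carry different barcodes")
    if p1.contig != p2.contig:
        return math.inf
    if p1.leftmost > p2.leftmost:
        raise InvalidParameterError("p1 must not start after p2")
    return float(max(0, p2.leftmost - p1.rightmost))


def _as_frame(placements) -> pd.DataFrame:
    if isinstance(placements, pd.DataFrame):
        missing = set(PLACEMENT_COLUMNS) - set(placements.columns)
        if missing:
            raise InvalidParameterError(f"placement frame missing {sorted(missing)}")
        return placements
    rows = [
        (p.read_id, p.barcode, p.contig, p.leftmost, p.rightmost) for p in placements
    ]
    return pd.DataFrame(rows, columns=list(PLACEMENT_COLUMNS))


# ---------------------------------------------------------------------------
# molecule reconstruction
# ---------------------------------------------------------------------------

def infer_fragments(
    placements,
    gap_kb: float = 50.0,
    min_pairs: int = 2,
    min_len_kb: float = 2.0,
    min_frags_per_partition: int = 3,
) -> list[InferredFragment]:
    """Chain same-barcode read placements into molecules and filter them.

    Placements are sorted by (barcode, contig, leftmost); a new molecule
    starts whenever the contig changes or the end-to-start gap between
    consecutive pair spans exceeds ``gap_kb`` kilobases.  Molecule span is
    the union of member spans.  Filters are applied in order: chain
    termination, then the per-molecule ``min_pairs`` / ``min_len_kb``
    floors, then removal of barcodes retaining fewer than
    ``min_frags_per_partition`` molecules.  Input order never matters.
    """
    df = _as_frame(placements)
    if df.empty:
        return []
    df = df.sort_values(
        ["barcode", "contig", "leftmost", "rightmost"], kind="mergesort"
    ).reset_index(drop=True)

    gap_bp = gap_kb * 1000.0
    barcode = df["barcode"].to_numpy()
    contig = df["contig"].to_numpy()
    left = df["leftmost"].to_numpy(dtype=np.int64)
    right = df["rightmost"].to_numpy(dtype=np.int64)

    new = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        same = (barcode[1:] == barcode[:-1]) & (contig[1:] == contig[:-1])
        gap = left[1:] - right[:-1]  # may be negative for overlaps
        new[1:] = ~(same & (gap <= gap_bp))
    group = np.cumsum(new) - 1
    bounds = np.flatnonzero(new).tolist() + [len(df)]
    read_ids = df["read_id"].to_numpy()

    fragments: list[InferredFragment] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        span_start = int(left[lo])
        span_end = int(right[lo:hi].max())
        n = hi - lo
        if n < min_pairs or span_end - span_start < min_len_kb * 1000.0:
            continue
        fragments.append(
            InferredFragment(
                barcode=str(barcode[lo]),
                contig=str(contig[lo]),
                start=span_start,
                end=span_end,
                n_read_pairs=n,
                read_ids=list(read_ids[lo:hi]),
            )
        )

    counts: dict[str, int] = {}
    for frag in fragments:
        counts[frag.barcode] = counts.get(frag.barcode, 0) + 1
    return [f for f in fragments if counts[f.barcode] >= min_frags_per_partition]


# ---------------------------------------------------------------------------
# library profiling
# ---------------------------------------------------------------------------

@dataclass
class LibraryProfile:
    """Summary of a reconstructed Linked-Read library."""

    n_fragments: int
    n_partitions: int
    fragments_per_partition: pd.Series  # index: per-barcode molecule count
    depth_per_fragment: np.ndarray  # fold coverage within each molecule
    length_summary: FragmentLengthSummary | None
    est_c_f: float
    est_c_r: float
    est_n_fp: float

    @property
    def is_empty(self) -> bool:
        return self.n_fragments == 0

    def to_tsvs(self, out_prefix: str | Path) -> list[str]:
        """Write the profile panels as TSV tables; returns the paths."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = []

        def _write(name: str, frame: pd.DataFrame) -> None:
            path = out_prefix.with_name(f"{out_prefix.name}_{name}.tsv")
            frame.to_csv(path, sep="\t", index=False)
            paths.append(str(path))

        fpp = self.fragments_per_partition.value_counts().sort_index()
        _write(
            "fragments_per_partition",
            pd.DataFrame(
                {"n_fragments": fpp.index, "n_partitions": fpp.to_numpy()}
            ),
        )
        hist, edges = np.histogram(self.depth_per_fragment, bins=50)
        _write(
            "depth_per_fragment",
            pd.DataFrame(
                {"depth_left": edges[:-1], "depth_right": edges[1:], "count": hist}
            ),
        )
        if self.length_summary is not None:
            _write("length_distribution", self.length_summary.distribution())
        summary = pd.DataFrame(
            {
                "n_fragments": [self.n_fragments],
                "n_partitions": [self.n_partitions],
                "mu_FL": [self.length_summary.mu_FL if self.length_summary else 0],
                "W_mu_FL": [self.length_summary.W_mu_FL if self.length_summary else 0],
                "est_C_F": [self.est_c_f],
                "est_C_R": [self.est_c_r],
                "est_N_FP": [self.est_n_fp],
            }
        )
        _write("summary", summary)
        return paths


def profile_library(
    fragments: Sequence[InferredFragment],
    reference_length: int,
    genomic_bases_per_pair_: int = genomic_bases_per_pair(150),
) -> LibraryProfile:
    """Estimate library parameters from reconstructed molecules.

    ``C_F`` is total molecule length over the haploid reference length;
    ``C_R`` is total genomic read bases over total molecule length;
    ``N_F/P`` is the mean molecule count per retained barcode.
    """
    if reference_length <= 0:
        raise InvalidParameterError("reference_length must be > 0")
    if not fragments:
        return LibraryProfile(
            n_fragments=0,
            n_partitions=0,
            fragments_per_partition=pd.Series(dtype=int),
            depth_per_fragment=np.empty(0),
            length_summary=None,
            est_c_f=0.0,
            est_c_r=0.0,
            est_n_fp=0.0,
        )
    lengths = np.array([f.length for f in fragments], dtype=float)
    pairs = np.array([f.n_read_pairs for f in fragments], dtype=float)
    barcodes = pd.Series([f.barcode for f in fragments])
    per_barcode = barcodes.value_counts()
    g = genomic_bases_per_pair_
    return LibraryProfile(
        n_fragments=len(fragments),
        n_partitions=len(per_barcode),
        fragments_per_partition=per_barcode,
        depth_per_fragment=pairs * g / lengths,
        length_summary=summarize_lengths(lengths),
        est_c_f=float(lengths.sum() / reference_length),
        est_c_r=float(pairs.sum() * g / lengths.sum()),
        est_n_fp=float(len(fragments) / len(per_barcode)),
    )


# ---------------------------------------------------------------------------
# barcode-aware subsampling
# ---------------------------------------------------------------------------

def subsample_reads(
    fragments: Sequence[InferredFragment],
    target_cr: float,
    seed: int = 0,
    genomic_bases_per_pair_: int = genomic_bases_per_pair(150),
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Thin each molecule's read pairs to an expected coverage ``target_cr``.

    Per molecule, ``round(target_cr * length / g)`` pairs are kept by
    uniform sampling without replacement, capped at the pairs available.
    Returns the retained read ids.
    """
    if not target_cr > 0:
        raise InvalidParameterError("target_cr must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    kept: list[str] = []
    for frag in fragments:
        want = round(target_cr * frag.length / genomic_bases_per_pair_)
        want = min(int(want), frag.n_read_pairs)
        if want >= frag.n_read_pairs:
            kept.extend(frag.read_ids)
        elif want > 0:
            idx = rng.choice(frag.n_read_pairs, size=want, replace=False)
            kept.extend(frag.read_ids[i] for i in sorted(idx))
    return kept


def subsample_fragments(
    fragments: Sequence[InferredFragment],
    target_cf: float,
    reference_length: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[InferredFragment]:
    """Drop whole molecules at random until ``C_F`` first falls to target.

    Molecules are removed one at a time in a random order until total
    molecule length over ``reference_length`` is <= ``target_cf``; if the
    input already satisfies the target it is returned unchanged.
    """
    if not target_cf > 0:
        raise InvalidParameterError("target_cf must be > 0")
    if reference_length <= 0:
        raise InvalidParameterError("reference_length must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = sum(f.length for f in fragments)
    target_bases = target_cf * reference_length
    if total <= target_bases:
        return list(fragments)
    drop: set[int] = set()
    for i in rng.permutation(len(fragments)):
        if total <= target_bases:
            break
        drop.add(int(i))
        total -= fragments[i].length
    return [f for i, f in enumerate(fragments) if i not in drop]


# ---------------------------------------------------------------------------
# placement readers
# ---------------------------------------------------------------------------

def placements_from_truth(
    path: str | Path, split_haplotypes: bool = True
) -> pd.DataFrame:
    """Build pair placements from the simulator's truth TSV.

    With ``split_haplotypes`` the placement contig is the haplotype-specific
    template contig (``<contig>_hap<k>``), i.e. reads are placed on the
    diploid template they were drawn from; without it, both haplotypes share
    the reference coordinate system, as they would after alignment to a
    haploid reference.
    """
    df = pd.read_csv(path, sep="\t")
    contig = df["contig"].astype(str)
    if split_haplotypes:
        contig = contig + "_hap" + df["haplotype"].astype(str)
    return pd.DataFrame(
        {
            "read_id": df["read_id"],
            "barcode": df["barcode"],
            "contig": contig,
            "leftmost": df["r1_start"].astype(np.int64),
            "rightmost": (df["r1_start"] + df["insert_len"]).astype(np.int64),
        }
    )


def placements_from_sam(
    path: str | Path, counters: MutableMapping[str, int] | None = None
) -> pd.DataFrame:
    """Build pair placements from a coordinate-sorted SAM/BAM with BX tags.

    One placement per proper pair, spanning from the leftmost mate's start
    to the rightmost mate's end (template length).  Secondary and
    supplementary alignments, unmapped reads or mates, duplicate-marked
    records, and records without a ``BX`` tag are skipped and counted.
    """
    import pysam

    if counters is None:
        counters = {}
    for key in ("no_bx", "secondary_supplementary", "unmapped", "duplicate", "used"):
        counters.setdefault(key, 0)

    rows = []
    with pysam.AlignmentFile(str(path)) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                counters["secondary_supplementary"] += 1
                continue
            if rec.is_unmapped or rec.mate_is_unmapped:
                counters["unmapped"] += 1
                continue
            if rec.is_duplicate:
                counters["duplicate"] += 1
                continue
            if not rec.has_tag("BX"):
                counters["no_bx"] += 1
                continue
            # count each pair once, from its leftmost mate
            if rec.template_length <= 0:
                continue
            counters["used"] += 1
            rows.append(
                (
                    rec.query_name,
                    rec.get_tag("BX"),
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_start + rec.template_length,
                )
            )
    return pd.DataFrame(rows, columns=list(PLACEMENT_COLUMNS))
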