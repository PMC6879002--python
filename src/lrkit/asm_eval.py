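"""Diploid-assembly evaluation.

Operates on standard assembler/aligner outputs rather than re-running them:
scaffolds come in as FASTA (haplotype labels in the headers), alignments as
PAF.  Provides:

* scaffold -> contig decomposition at runs of >= 10 ``N``;
* N50/NA50 contiguity statistics, with NA50 computed after breaking
  sequences at alignment-detected misassembly signatures (target switch,
  strand flip, or indel-like gap disagreement between query and target);
* diploid / haploid genome-fraction classification on 500-bp windows — a
  window is *diploid* when covered by at least one contig from each
  haplotype and *haploid* when covered by exactly one haplotype;
* the chance expectation for multi-assembly diploid-region overlap
  (product of the per-assembly diploid fractions, i.e. independence) with
  a 1-df chi-square goodness-of-fit test;
* phase-block statistics operationalized as maximal runs of diploid
  windows.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .params import EmptyInputError, InvalidParameterError

__all__ = [
    "AssemblyRecord",
    "AlignmentBlock",
    "WindowClassification",
    "Chi2Result",
    "parse_haplotype_label",
    "read_assembly_fasta",
    "break_scaffolds",
    "nx",
    "break_at_misassemblies",
    "classify_windows",
    "chance_overlap",
    "overlap_chi2",
    "diploid_length_report",
    "phase_block_n50",
    "parse_paf",
]

UNPHASED = "unphased"


@dataclass
class AssemblyRecord:
    """A scaffold or contig with its haplotype label."""

    name: str
    sequence: str
    haplotype_label: int | str = UNPHASED  # 1, 2, or "unphased"
    origin_scaffold: str | None = None
    offset: int = 0  # start within the origin scaffold

    def __len__(self) -> int:
        return len(self.sequence)


def parse_haplotype_label(name: str) -> int | str:
    """Haplotype from a sequence-name suffix: ``/1``, ``/2`` (or ``_hap1``/``_hap2``)."""
    base = name.split(".")[0] if re.search(r"\.\d+$", name) else name
    for hap in (1, 2):
        if base.endswith((f"/{hap}", f"_hap{hap}")):
            return hap
    return UNPHASED


def read_assembly_fasta(path: str | Path) -> list[AssemblyRecord]:
    """Read assembly sequences, parsing haplotype labels from the headers."""
    records: list[AssemblyRecord] = []
    name = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is not None:
            seq = "".join(chunks).upper()
            records.append(
                AssemblyRecord(name, seq, haplotype_label=parse_haplotype_label(name))
            )

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            _flush()
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line.strip())
    _flush()
    return records


# ---------------------------------------------------------------------------
# scaffold -> contig decomposition
# ---------------------------------------------------------------------------

def break_scaffolds(
    scaffolds: Iterable[AssemblyRecord], min_n_run: int = 10
) -> list[AssemblyRecord]:
    """Split scaffolds into contigs at every N-run of length >= ``min_n_run``.

    Shorter N-runs stay inside contigs.  Contigs inherit the scaffold's
    haplotype label and record their origin and offset, so placing every
    contig at its offset (on an all-``N`` canvas) reproduces the scaffold.
    """
    if min_n_run < 1:
        raise InvalidParameterError("min_n_run must be >= 1")
    splitter = re.compile(f"N{{{min_n_run},}}")
    contigs: list[AssemblyRecord] = []
    for scaf in scaffolds:
        cursor = 0
        serial = 0
        for match in splitter.finditer(scaf.sequence):
            piece = scaf.sequence[cursor : match.start()]
            if piece:
                serial += 1
                contigs.append(
                    AssemblyRecord(
                        name=f"{scaf.name}.{serial}",
                        sequence=piece,
                        haplotype_label=scaf.haplotype_label,
                        origin_scaffold=scaf.name,
                        offset=cursor,
                    )
                )
            cursor = match.end()
        piece = scaf.sequence[cursor:]
        if piece:
            serial += 1
            contigs.append(
                AssemblyRecord(
                    name=f"{scaf.name}.{serial}",
                    sequence=piece,
                    haplotype_label=scaf.haplotype_label,
                    origin_scaffold=scaf.name,
                    offset=cursor,
                )
            )
    return contigs


# ---------------------------------------------------------------------------
# contiguity statistics
# ---------------------------------------------------------------------------

def nx(lengths: Sequence[float], x: float = 50.0) -> float:
    """The Nx statistic: largest L such that pieces >= L hold >= x% of bases."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("no lengths supplied")
    if np.any(arr <= 0):
        raise InvalidParameterError("lengths must be positive")
    if not (0 < x <= 100):
        raise InvalidParameterError("x must lie in (0, 100]")
    arr = np.sort(arr)[::-1]
    cum = np.cumsum(arr)
    threshold = x / 100.0 * cum[-1]
    return float(arr[np.searchsorted(cum, threshold - 1e-9)])


@dataclass(frozen=True)
class AlignmentBlock:
    """One alignment block (PAF row), 0-based half-open on both sides."""

    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str  # "+" or "-"
    target: str
    target_start: int
    target_end: int
    aln_len: int = 0
    mapq: int = 60

    def __post_init__(self) -> None:
        if not (self.query_start < self.query_end and self.target_start < self.target_end):
            raise InvalidParameterError("alignment block intervals must be nonempty")


def parse_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read minimap2-style PAF rows (first 12 columns) into blocks."""
    blocks: list[AlignmentBlock] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) < 12:
            raise InvalidParameterError(f"PAF row has {len(cols)} columns (< 12)")
        blocks.append(
            AlignmentBlock(
                query=cols[0],
                query_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                target=cols[5],
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                aln_len=int(cols[10]),
                mapq=int(cols[11]),
            )
        )
    return blocks


def _resolve_query_overlaps(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Sort by query start; on query-side overlap keep the longer block."""
    kept: list[AlignmentBlock] = []
    for blk in sorted(blocks, key=lambda b: (b.query_start, b.query_end)):
        if kept and blk.query_start < kept[-1].query_end:
            prev = kept[-1]
            if (blk.query_end - blk.query_start) > (prev.query_end - prev.query_start):
                kept[-1] = blk
            continue
        kept.append(blk)
    return kept


def break_at_misassemblies(
    blocks: Sequence[AlignmentBlock],
    query_lengths: Mapping[str, int] | None = None,
    max_gap_bp: int = 1000,
    min_block_bp: int = 500,
    min_mapq: int = 0,
    min_query_len: int = 500,
) -> list[float]:
    """Break query sequences at alignment-detected misassembly signatures.

    A breakpoint is declared between consecutive query-sorted blocks when
    (a) the target contigs differ, (b) the strands differ, or (c) the
    target-side and query-side gaps disagree by more than ``max_gap_bp``.
    The query length is split at the query-side midpoints of the
    breakpoints.  Queries with no surviving alignment contribute their full
    length unbroken (conservative).  Returns the broken lengths, the input
    to an NA50 computation via :func:`nx`.
    """
    lengths: dict[str, int] = dict(query_lengths or {})
    by_query: dict[str, list[AlignmentBlock]] = {}
    for blk in blocks:
        lengths.setdefault(blk.query, blk.query_len)
        if blk.query_end - blk.query_start < min_block_bp or blk.mapq < min_mapq:
            continue
        by_query.setdefault(blk.query, []).append(blk)

    broken: list[float] = []
    for query, qlen in lengths.items():
        if qlen < min_query_len:
            continue
        qblocks = _resolve_query_overlaps(by_query.get(query, []))
        if not qblocks:
            broken.append(float(qlen))
            continue
        cuts: list[int] = []
        for prev, cur in zip(qblocks, qblocks[1:]):
            split = (
                prev.target != cur.target
                or prev.strand != cur.strand
            )
            if not split:
                query_gap = cur.query_start - prev.query_end
                if prev.strand == "+":
                    target_gap = cur.target_start - prev.target_end
                else:
                    target_gap = prev.target_start - cur.target_end
                split = abs(target_gap - query_gap) > max_gap_bp
            if split:
                cuts.append((prev.query_end + cur.query_start) // 2)
        edges = [0] + cuts + [qlen]
        broken.extend(float(b - a) for a, b in zip(edges, edges[1:]) if b > a)
    return broken


# ---------------------------------------------------------------------------
# window classification
# ---------------------------------------------------------------------------

WINDOW_CLASSES = ("uncovered", "haploid", "diploid", "excess")
_UNCOVERED, _HAPLOID, _DIPLOID, _EXCESS = range(4)


@dataclass
class WindowClassification:
    """Per-window diploid/haploid classes over the reference genome.

    ``classes[contig]`` holds one small-int code per full window (see
    :data:`WINDOW_CLASSES`); partial terminal windows are not scored.
    """

    window: int
    classes: dict[str, np.ndarray]
    hap_masks: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)

    @property
    def n_windows(self) -> int:
        return int(sum(len(arr) for arr in self.classes.values()))

    def fractions(self) -> dict[str, float]:
        total = self.n_windows
        if total == 0:
            raise EmptyInputError("no windows classified")
        counts = np.zeros(4, dtype=np.int64)
        for arr in self.classes.values():
            counts += np.bincount(arr, minlength=4)
        out = {
            name: counts[code] / total
            for code, name in enumerate(WINDOW_CLASSES)
        }
        out["overall"] = 1.0 - out["uncovered"]
        return out

    def diploid_regions(self) -> list[tuple[str, int, int]]:
        """Maximal runs of diploid windows as genomic intervals."""
        regions: list[tuple[str, int, int]] = []
        for contig, arr in self.classes.items():
            dip = arr == _DIPLOID
            if not dip.any():
                continue
            edges = np.flatnonzero(np.diff(np.r_[0, dip.view(np.int8), 0]))
            for lo, hi in zip(edges[::2], edges[1::2]):
                regions.append((contig, int(lo) * self.window, int(hi) * self.window))
        return regions

    def write_beds(self, out_prefix: str | Path) -> dict[str, str]:
        """Write the diploid-region BED and the per-window class BED."""
        from .template import write_bed

        out_prefix = Path(out_prefix)
        dip_path = out_prefix.with_name(out_prefix.name + "_diploid_regions.bed")
        write_bed(self.diploid_regions(), dip_path)
        win_path = out_prefix.with_name(out_prefix.name + "_window_classes.bed")
        with open(win_path, "w") as fh:
            for contig, arr in self.classes.items():
                for i, code in enumerate(arr):
                    fh.write(
                        f"{contig}\t{i * self.window}\t{(i + 1) * self.window}"
                        f"\t{WINDOW_CLASSES[code]}\n"
                    )
        return {"diploid_regions": str(dip_path), "window_classes": str(win_path)}


def _window_cover_mask(
    intervals: list[tuple[int, int]], n_windows: int, window: int, min_cov_frac: float
) -> np.ndarray:
    """Windows whose covered-base fraction from merged intervals >= threshold."""
    cov = np.zeros(n_windows, dtype=np.int64)
    limit = n_windows * window
    for start, end in intervals:
        start, end = max(0, start), min(end, limit)
        if start >= end:
            continue
        w0, w1 = start // window, (end - 1) // window
        if w0 == w1:
            cov[w0] += end - start
        else:
            cov[w0] += (w0 + 1) * window - start
            cov[w1] += end - w1 * window
            if w1 > w0 + 1:
                cov[w0 + 1 : w1] += window
    return cov >= min_cov_frac * window


def classify_windows(
    blocks: Sequence[AlignmentBlock],
    reference_lengths: Mapping[str, int],
    haplotype_labels: Mapping[str, int | str] | None = None,
    window: int = 500,
    min_cov_frac: float = 1.0,
) -> WindowClassification:
    """Classify fixed-size reference windows by haplotype coverage.

    A window counts as covered by an assembly contig when that contig's
    merged alignment blocks span at least ``min_cov_frac`` of it.  Diploid
    windows are covered by at least one haplotype-1 and one haplotype-2
    contig; haploid windows by exactly one of the two haplotypes.  Windows
    covered only by unlabeled contigs count toward overall coverage (class
    ``excess``); unlabeled contigs trigger a warning.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    if not (0 < min_cov_frac <= 1):
        raise InvalidParameterError("min_cov_frac must lie in (0, 1]")
    labels = haplotype_labels or {}

    def _label(query: str) -> int | str:
        return labels.get(query, parse_haplotype_label(query))

    n_win = {c: length // window for c, length in reference_lengths.items()}
    hap1 = {c: np.zeros(n, dtype=bool) for c, n in n_win.items()}
    hap2 = {c: np.zeros(n, dtype=bool) for c, n in n_win.items()}
    other = {c: np.zeros(n, dtype=bool) for c, n in n_win.items()}

    by_query_contig: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for blk in blocks:
        if blk.target not in n_win:
            raise InvalidParameterError(
                f"alignment targets unknown reference contig {blk.target!r}"
            )
        by_query_contig.setdefault((blk.query, blk.target), []).append(
            (blk.target_start, blk.target_end)
        )

    warned = False
    from .template import merge_intervals

    for (query, contig), intervals in by_query_contig.items():
        mask = _window_cover_mask(
            merge_intervals(intervals), n_win[contig], window, min_cov_frac
        )
        label = _label(query)
        if label == 1:
            hap1[contig] |= mask
        elif label == 2:
            hap2[contig] |= mask
        else:
            if not warned:
                warnings.warn(
                    f"unlabeled contig {query!r}: counted toward overall "
                    "coverage only",
                    stacklevel=2,
                )
                warned = True
            other[contig] |= mask

    classes: dict[str, np.ndarray] = {}
    for contig, n in n_win.items():
        arr = np.full(n, _UNCOVERED, dtype=np.int8)
        arr[other[contig]] = _EXCESS
        arr[hap1[contig] ^ hap2[contig]] = _HAPLOID
        arr[hap1[contig] & hap2[contig]] = _DIPLOID
        classes[contig] = arr
    return WindowClassification(
        window=window,
        classes=classes,
        hap_masks={c: (hap1[c], hap2[c]) for c in n_win},
    )


# ---------------------------------------------------------------------------
# multi-assembly overlap
# ---------------------------------------------------------------------------

def chance_overlap(fractions: Sequence[float]) -> float:
    """Expected overlap fraction under independence: the product."""
    if len(fractions) == 0:
        raise EmptyInputError("no fractions supplied")
    product = 1.0
    for frac in fractions:
        if not (0 <= frac <= 1):
            raise InvalidParameterError(f"fraction {frac} outside [0, 1]")
        product *= frac
    return product


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    low_expected_count: bool  # an expected cell count is < 5


def overlap_chi2(
    observed_overlap_windows: int, total_windows: int, expected_fraction: float
) -> Chi2Result:
    """1-df goodness-of-fit chi-square for observed vs chance overlap.

    Compares ``(observed, total - observed)`` against
    ``(total * p, total * (1 - p))``.
    """
    if not (0 < expected_fraction < 1):
        raise InvalidParameterError("expected_fraction must lie in (0, 1)")
    if not (0 <= observed_overlap_windows <= total_windows):
        raise InvalidParameterError("observed must lie in [0, total]")
    expected = np.array(
        [
            total_windows * expected_fraction,
            total_windows * (1 - expected_fraction),
        ]
    )
    observed = np.array(
        [observed_overlap_windows, total_windows - observed_overlap_windows]
    )
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return Chi2Result(
        statistic=statistic,
        p_value=p_value,
        low_expected_count=bool(expected.min() < 5),
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def diploid_length_report(
    contigs: Sequence[AssemblyRecord],
    classification: WindowClassification | None = None,
    min_contig_len: int = 500,
    designated_regions: Sequence[tuple[str, int, int]] | None = None,
) -> dict[str, float]:
    """Assembly-level diploidy report.

    Totals count contigs longer than ``min_contig_len``; the "megabubble"
    length is the haplotype-labeled share of that total.  When a window
    classification is supplied the overall/diploid/haploid genome fractions
    are included, and ``designated_regions`` (e.g. the hemizygous
    non-pseudoautosomal X) get their haploid-window fraction reported.
    """
    sized = [c for c in contigs if len(c) > min_contig_len]
    total = sum(len(c) for c in sized)
    labeled = sum(len(c) for c in sized if c.haplotype_label in (1, 2))
    report: dict[str, float] = {
        "total_contig_length": float(total),
        "megabubble_contig_length": float(labeled),
        "megabubble_percent": 100.0 * labeled / total if total else 0.0,
    }
    if classification is not None:
        fracs = classification.fractions()
        report["overall_percent"] = 100.0 * fracs["overall"]
        report["diploid_percent"] = 100.0 * fracs["diploid"]
        report["haploid_percent"] = 100.0 * fracs["haploid"]
        if designated_regions:
            window = classification.window
            n_total = 0
            n_haploid = 0
            for contig, start, end in designated_regions:
                arr = classification.classes.get(contig)
                if arr is None:
                    continue
                w0 = (start + window - 1) // window
                w1 = min(end // window, len(arr))
                if w1 > w0:
                    n_total += w1 - w0
                    n_haploid += int(np.sum(arr[w0:w1] == _HAPLOID))
            if n_total:
                report["designated_haploid_percent"] = 100.0 * n_haploid / n_total
    return report


def phase_block_n50(classification: WindowClassification) -> float:
    """N50 of maximal diploid-run lengths (the phase-block proxy)."""
    runs = [end - start for _, start, end in classification.diploid_regions()]
    if not runs:
        raise EmptyInputError("no diploid windows found")
    return nx(runs, 50.0)
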