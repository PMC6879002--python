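"""Linked-Read library simulation.

Mirrors the droplet (GEM) workflow of 10x Chromium library preparation in
three stages:

1. **Shearing** — each haplotype of the diploid template is copied whole
   and sheared into molecules whose lengths follow an exponential
   distribution with mean ``muFL``; copies are produced until the target
   physical coverage ``C_F`` (accounted against the haploid reference
   length, split evenly between haplotypes) is reached.
2. **Partitioning** — molecules are pooled and dealt at random into
   barcoded partitions whose sizes are Poisson(``N_F/P``); every molecule
   in a partition shares the partition's unique 16-base barcode.
3. **Read generation** — each molecule is sampled with paired-end short
   reads to mean per-molecule depth ``C_R``; the first 16 bases of every
   forward read are overwritten with the barcode, followed by a 7-base
   ``N`` spacer, exactly as in real Linked-Read FASTQs.

Output is a pair of (gzip) FASTQ files plus a plain-text truth table
recording, for every read pair, the molecule and haplotype it came from —
the alignment-free ground truth consumed by :mod:`lrkit.infer`.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, MutableMapping

import numpy as np

from .params import (
    BARCODE_LEN,
    MASKED_PREFIX,
    MAX_BARCODES,
    N_SPACER,
    EmptyInputError,
    InvalidParameterError,
    genomic_bases_per_pair,
)
from .template import DiploidTemplate

__all__ = [
    "Fragment",
    "Partition",
    "ReadPairRecord",
    "DegenerateLibraryError",
    "shear_fragments",
    "allocate_partitions",
    "generate_reads",
    "write_linked_fastq",
    "revcomp",
]


class DegenerateLibraryError(RuntimeError):
    """Requested parameters produce no usable fragments."""


_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class Fragment:
    """One sheared long DNA molecule (0-based half-open interval)."""

    fragment_id: int
    haplotype: int  # 1 or 2
    contig: str
    start: int
    end: int
    partition_id: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidParameterError("fragment requires 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Partition:
    """A barcoded droplet: a set of fragments sharing one barcode."""

    partition_id: int
    barcode: str
    fragment_ids: list[int]


@dataclass
class ReadPairRecord:
    """A simulated read pair with its full truth provenance."""

    read_id: str
    barcode: str
    partition_id: int
    fragment_id: int
    haplotype: int
    contig: str
    frag_start: int
    frag_end: int
    r1_start: int  # template coordinate of the forward read start
    r2_start: int  # template coordinate of the reverse read start
    insert_len: int
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str


# ---------------------------------------------------------------------------
# step 1: shearing
# ---------------------------------------------------------------------------

def shear_fragments(
    template: DiploidTemplate,
    mu_fl: float,
    c_f: float,
    min_len: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Shear whole-genome copies of each haplotype into long molecules.

    Each copy is cut from position 0 by successive exponential(``mu_fl``)
    lengths until the contig end (the last piece is truncated there);
    pieces shorter than ``min_len`` are discarded.  Copies accumulate until
    each haplotype holds at least ``c_f / 2`` fold of the haploid reference
    length, then randomly chosen fragments are dropped so the realized
    physical coverage sits within 1% of the target.
    """
    if not mu_fl > min_len:
        raise InvalidParameterError("mu_fl must exceed min_len")
    if min_len < 1:
        raise InvalidParameterError("min_len must be >= 1")
    if not c_f > 0:
        raise InvalidParameterError("c_f must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)

    ref_len = template.source_len
    target_per_hap = (c_f / 2.0) * ref_len
    raw: list[tuple[int, str, int, int]] = []  # (hap, contig, start, end)

    for hap in (1, 2):
        pieces: list[tuple[str, int, int]] = []
        total = 0
        while total < target_per_hap:
            added = 0
            for contig, length in template.ref_lengths.items():
                pos = 0
                while pos < length:
                    piece = max(1, int(rng.exponential(mu_fl)))
                    end = min(pos + piece, length)
                    if end - pos >= min_len:
                        pieces.append((contig, pos, end))
                        added += end - pos
                    pos = end
            if added == 0:
                raise DegenerateLibraryError(
                    "shearing produced no fragment >= min_len; "
                    "check min_len against contig lengths"
                )
            total += added
        # drop random excess so realized coverage hugs the target
        keep = np.ones(len(pieces), dtype=bool)
        for i in rng.permutation(len(pieces)):
            flen = pieces[i][2] - pieces[i][1]
            if total - flen >= target_per_hap:
                keep[i] = False
                total -= flen
        raw.extend(
            (hap, contig, start, end)
            for i, (contig, start, end) in enumerate(pieces)
            if keep[i]
        )

    if not raw:
        raise DegenerateLibraryError("no fragments produced")
    raw.sort()
    return [
        Fragment(fragment_id=i, haplotype=h, contig=c, start=s, end=e)
        for i, (h, c, s, e) in enumerate(raw)
    ]


# ---------------------------------------------------------------------------
# step 2: partition allocation
# ---------------------------------------------------------------------------

def _random_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    """``n`` distinct random 16-mers over ACGT."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), BARCODE_LEN))
        for row in draw:
            bc = "".join("ACGT"[b] for b in row)
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def allocate_partitions(
    fragments: list[Fragment],
    n_fp: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[Partition]:
    """Deal fragments into barcoded partitions of Poisson(``n_fp``) size.

    Zero draws are redrawn (an empty droplet holds no molecules and is
    invisible); fragments are assigned without replacement in random order,
    so the final partition may hold fewer than its drawn size.  Mutates
    ``fragment.partition_id`` in place and returns the partitions.
    """
    if not n_fp > 0:
        raise InvalidParameterError("n_fp must be > 0")
    if not fragments:
        return []
    rng = rng if rng is not None else np.random.default_rng(seed)

    order = rng.permutation(len(fragments))
    sizes: list[int] = []
    assigned = 0
    while assigned < len(fragments):
        k = 0
        while k == 0:
            k = int(rng.poisson(n_fp))
        sizes.append(k)
        assigned += k

    n_partitions = len(sizes)
    if n_partitions > MAX_BARCODES:
        warnings.warn(
            f"{n_partitions} partitions exceeds the {MAX_BARCODES} barcode "
            "whitelist limit of downstream assemblers",
            stacklevel=2,
        )
    barcodes = _random_barcodes(rng, n_partitions)

    partitions: list[Partition] = []
    cursor = 0
    for pid, size in enumerate(sizes):
        members = order[cursor : cursor + size]
        cursor += size
        if len(members) == 0:
            break
        frag_ids = []
        for idx in members:
            fragments[idx].partition_id = pid
            frag_ids.append(fragments[idx].fragment_id)
        partitions.append(
            Partition(partition_id=pid, barcode=barcodes[pid], fragment_ids=frag_ids)
        )
    return partitions


# ---------------------------------------------------------------------------
# step 3: read generation
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitution errors at ``rate`` to a sequence."""
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq.encode())
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        base = chr(arr[pos])
        choices = [b for b in "ACGT" if b != base] or list("ACGT")
        arr[pos] = ord(choices[rng.integers(len(choices))])
    return arr.decode()


def generate_reads(
    template: DiploidTemplate,
    fragments: list[Fragment],
    partitions: list[Partition],
    c_r: float,
    read_len: int = 150,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    counters: MutableMapping[str, int] | None = None,
) -> Iterator[ReadPairRecord]:
    """Yield barcoded paired-end reads at mean per-fragment coverage ``c_r``.

    Per fragment of length ``L`` the pair count is Poisson(``c_r * L / g``)
    with ``g`` the genomic bases per pair (277 under 2 x 150 bp defaults),
    reflecting the stochastic capture of molecule sequence in the droplet.
    Inserts are round(Normal(``insert_mean``, ``insert_sd``)) clamped to
    ``[2 * read_len, L]``; the forward read's first 23 bases are replaced
    by barcode + ``NNNNNNN``.  Fragments shorter than ``2 * read_len`` are
    skipped and counted in ``counters['fragments_too_short']``.
    """
    if not c_r > 0:
        raise InvalidParameterError("c_r must be > 0")
    if insert_mean < 2 * read_len:
        raise InvalidParameterError("insert_mean must be >= 2 * read_len")
    if not (0 <= error_rate < 1):
        raise InvalidParameterError("error_rate must lie in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if counters is None:
        counters = {}
    counters.setdefault("fragments_too_short", 0)
    counters.setdefault("pairs_emitted", 0)

    barcode_of = {p.partition_id: p.barcode for p in partitions}
    g = genomic_bases_per_pair(read_len)
    q_char = chr(33 + round(-10 * math.log10(max(error_rate, 1e-4))))
    qual = q_char * read_len
    spacer = "N" * N_SPACER

    for frag in fragments:
        L = frag.length
        if L < 2 * read_len:
            counters["fragments_too_short"] += 1
            continue
        if frag.partition_id is None:
            raise InvalidParameterError(
                f"fragment {frag.fragment_id} has no partition; "
                "run allocate_partitions first"
            )
        n_pairs = int(rng.poisson(c_r * L / g))
        if n_pairs == 0:
            continue
        barcode = barcode_of[frag.partition_id]
        hap_seq = template.haplotype(frag.contig, frag.haplotype)
        inserts = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs))
        inserts = np.clip(inserts, 2 * read_len, L).astype(np.int64)
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
        for serial, (ins, off) in enumerate(zip(inserts, starts)):
            a = frag.start + int(off)
            ins = int(ins)
            r1 = hap_seq[a : a + read_len]
            r2 = revcomp(hap_seq[a + ins - read_len : a + ins])
            if error_rate > 0:
                r1 = _mutate(r1, error_rate, rng)
                r2 = _mutate(r2, error_rate, rng)
            r1 = barcode + spacer + r1[MASKED_PREFIX:]
            counters["pairs_emitted"] += 1
            yield ReadPairRecord(
                read_id=f"sim:{frag.fragment_id}:{serial}",
                barcode=barcode,
                partition_id=frag.partition_id,
                fragment_id=frag.fragment_id,
                haplotype=frag.haplotype,
                contig=frag.contig,
                frag_start=frag.start,
                frag_end=frag.end,
                r1_start=a,
                r2_start=a + ins - read_len,
                insert_len=ins,
                r1_seq=r1,
                r2_seq=r2,
                r1_qual=qual,
                r2_qual=qual,
            )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = (
    "read_id",
    "barcode",
    "partition_id",
    "fragment_id",
    "haplotype",
    "contig",
    "frag_start",
    "frag_end",
    "r1_start",
    "r2_start",
    "insert_len",
)


def write_linked_fastq(
    records: Iterable[ReadPairRecord],
    out_prefix: str | Path,
    compress: bool = True,
) -> dict[str, str | int]:
    """Write R1/R2 FASTQ files and the truth TSV sidecar.

    Mate order is preserved between the two FASTQs; the truth TSV holds one
    row per pair with full provenance (:data:`TRUTH_COLUMNS`).  Returns a
    summary dict with the paths and the pair count.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    suffix = ".fq.gz" if compress else ".fq"
    r1_path = out_prefix.with_name(out_prefix.name + "_R1" + suffix)
    r2_path = out_prefix.with_name(out_prefix.name + "_R2" + suffix)
    truth_path = out_prefix.with_name(out_prefix.name + "_truth.tsv")
    opener = (lambda p: gzip.open(p, "wt")) if compress else (lambda p: open(p, "w"))

    n = 0
    with opener(r1_path) as r1, opener(r2_path) as r2, open(truth_path, "w") as truth:
        truth.write("\t".join(TRUTH_COLUMNS) + "\n")
        for rec in records:
            r1.write(f"@{rec.read_id}\n{rec.r1_seq}\n+\n{rec.r1_qual}\n")
            r2.write(f"@{rec.read_id}\n{rec.r2_seq}\n+\n{rec.r2_qual}\n")
            truth.write(
                f"{rec.read_id}\t{rec.barcode}\t{rec.partition_id}"
                f"\t{rec.fragment_id}\t{rec.haplotype}\t{rec.contig}"
                f"\t{rec.frag_start}\t{rec.frag_end}\t{rec.r1_start}"
                f"\t{rec.r2_start}\t{rec.insert_len}\n"
            )
            n += 1
    if n == 0:
        raise EmptyInputError("no read pairs were generated")
    return {
        "r1": str(r1_path),
        "r2": str(r2_path),
        "truth": str(truth_path),
        "n_pairs": n,
    }
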