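"""Diploid template construction.

The simulator needs a phased diploid genome to shear.  Following the 10x
simulation workflow, the template is built by duplicating a (haploid)
reference into two haplotypes and inserting SNVs only — no indels — so both
haplotypes keep the reference coordinate system:

* inside user-supplied high-confidence regions, a supplied call set is
  inserted with its own genotypes;
* everywhere else, random SNVs are placed at 1 SNV per kb in expectation
  with a 2:1 heterozygous:homozygous ratio (both configurable).

A synthetic-reference generator is bundled so no external genome download
is ever required; it can also plant interspersed repeat copies for
repeat-sensitivity experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (
    ConsistencyError,
    EmptyInputError,
    InvalidParameterError,
    stage_rng,
)

__all__ = [
    "SyntheticReferenceSpec",
    "DiploidTemplate",
    "SnvCall",
    "RepeatPlacementError",
    "generate_reference",
    "build_template",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "read_snv_calls",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")
# the three substitution choices for each reference base
_ALT_CHOICES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

HOM = "hom"
HET_HAP1 = "het_hap1"
HET_HAP2 = "het_hap2"


class RepeatPlacementError(RuntimeError):
    """Requested repeat copies cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# synthetic reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticReferenceSpec:
    """Recipe for a random reference genome used as simulation input."""

    n_contigs: int = 1
    contig_len: int = 1_000_000
    gc_content: float = 0.5
    repeat_unit_len: int = 0
    repeat_copies: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contig_len <= 0 or self.n_contigs <= 0:
            raise InvalidParameterError("contig_len and n_contigs must be > 0")
        if not (0 < self.gc_content < 1):
            raise InvalidParameterError("gc_content must lie in (0, 1)")
        if self.repeat_copies > 0 and self.repeat_unit_len <= 0:
            raise InvalidParameterError(
                "repeat_unit_len must be > 0 when repeat_copies > 0"
            )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=probs)


def generate_reference(
    spec: SyntheticReferenceSpec,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Generate random reference contigs, optionally planting repeats.

    Returns ``(contigs, repeat_annotation)`` where the annotation lists
    ``(contig, start, end)`` of every planted repeat copy (0-based
    half-open).  A single fixed random repeat unit is reused for all copies,
    standing in for an interspersed repeat family.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    contigs: dict[str, np.ndarray] = {
        f"contig_{i + 1}": _random_bases(rng, spec.contig_len, spec.gc_content)
        for i in range(spec.n_contigs)
    }
    annotation: list[tuple[str, int, int]] = []
    if spec.repeat_copies > 0:
        unit = _random_bases(rng, spec.repeat_unit_len, spec.gc_content)
        names = list(contigs)
        placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        for _ in range(spec.repeat_copies):
            for _try in range(1000):
                name = names[rng.integers(len(names))]
                if spec.contig_len < spec.repeat_unit_len:
                    break
                start = int(rng.integers(0, spec.contig_len - spec.repeat_unit_len + 1))
                end = start + spec.repeat_unit_len
                if all(end <= s or start >= e for s, e in placed[name]):
                    placed[name].append((start, end))
                    contigs[name][start:end] = unit
                    annotation.append((name, start, end))
                    break
            else:
                raise RepeatPlacementError(
                    "could not place all repeat copies without overlap"
                )
        annotation.sort()
    return {k: v.tobytes().decode() for k, v in contigs.items()}, annotation


# ---------------------------------------------------------------------------
# interval and call-set plumbing
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping 0-based half-open intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file (first three columns) into merged intervals."""
    regions: dict[str, list[tuple[int, int]]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        contig, start, end = line.split("\t")[:3]
        regions.setdefault(contig, []).append((int(start), int(end)))
    return {contig: merge_intervals(ivals) for contig, ivals in regions.items()}


def write_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


@dataclass(frozen=True)
class SnvCall:
    """One supplied SNV with its genotype.

    ``zygosity`` is one of ``hom``, ``het_hap1``, ``het_hap2``; ``None``
    means heterozygous with unspecified phase (a haplotype is assigned by
    fair coin when the template is built).
    """

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str | None


def read_snv_calls(path: str | Path) -> list[SnvCall]:
    """Read biallelic SNVs with GT from a VCF (4.2) file.

    Phased genotypes ``1|0`` / ``0|1`` map to haplotype 1 / 2; unphased
    ``0/1`` is left unphased; ``1/1`` is homozygous.  Non-SNV or non-GT
    records are skipped.
    """
    import pysam

    calls: list[SnvCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            sample = rec.samples[next(iter(rec.samples))]
            gt = sample.get("GT")
            if gt is None or None in gt:
                continue
            if gt == (1, 1):
                zyg = HOM
            elif set(gt) == {0, 1}:
                if sample.phased:
                    zyg = HET_HAP1 if gt[0] == 1 else HET_HAP2
                else:
                    zyg = None
            else:
                continue
            calls.append(SnvCall(rec.contig, rec.pos - 1, ref, alt, zyg))
    return calls


# ---------------------------------------------------------------------------
# the diploid template
# ---------------------------------------------------------------------------

@dataclass
class DiploidTemplate:
    """Two SNV-divergent haplotypes per contig plus the SNV table.

    Haplotype sequences have exactly the reference length (SNV-only
    divergence).  ``snv_table`` columns: ``contig``, ``pos`` (0-based),
    ``ref``, ``alt``, ``zygosity``.
    """

    haplotypes: dict[str, tuple[str, str]]
    snv_table: pd.DataFrame
    ref_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_lengths:
            self.ref_lengths = {
                contig: len(h1) for contig, (h1, _) in self.haplotypes.items()
            }

    @property
    def source_len(self) -> int:
        """Haploid reference length in bp."""
        return sum(self.ref_lengths.values())

    def haplotype(self, contig: str, hap: int) -> str:
        return self.haplotypes[contig][hap - 1]

    def write_fasta(self, path: str | Path) -> None:
        """Write both haplotypes with ``_hap1`` / ``_hap2`` name suffixes."""
        records = {}
        for contig, (h1, h2) in self.haplotypes.items():
            records[f"{contig}_hap1"] = h1
            records[f"{contig}_hap2"] = h2
        write_fasta(records, path)

    def write_vcf(self, path: str | Path) -> None:
        """Emit the SNV table as a minimal VCF 4.2 with phased GT."""
        gt = {HOM: "1|1", HET_HAP1: "1|0", HET_HAP2: "0|1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for contig, length in self.ref_lengths.items():
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n"
            )
            for row in self.snv_table.itertuples(index=False):
                fh.write(
                    f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}"
                    f"\t.\tPASS\t.\tGT\t{gt[row.zygosity]}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}`` (uppercased)."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(
    records: Mapping[str, str], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _region_mask(length: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        if start < 0 or end > length:
            raise InvalidParameterError(
                f"interval ({start}, {end}) outside contig of length {length}"
            )
        mask[start:end] = True
    return mask


def build_template(
    reference: Mapping[str, str],
    hc_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    snv_calls: Sequence[SnvCall] | None = None,
    lc_density: float = 1.0,
    het_hom_ratio: float = 2.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> DiploidTemplate:
    """Duplicate a reference into two haplotypes and insert SNVs.

    Supplied calls falling inside the high-confidence regions are inserted
    with their own genotypes.  Outside those regions (everywhere, when no
    regions are given) random SNVs are placed per base with probability
    ``lc_density / 1000``, with zygosity heterozygous:homozygous in
    ``het_hom_ratio : 1`` and the heterozygous haplotype chosen by fair
    coin; the alternate allele is uniform over the three non-reference
    bases.  ``N`` reference bases are never mutated.

    When calls are supplied without high-confidence regions, all calls are
    inserted and random SNVs avoid the call positions.
    """
    if not reference:
        raise EmptyInputError("reference has no contigs")
    if lc_density < 0:
        raise InvalidParameterError("lc_density must be >= 0")
    if het_hom_ratio < 0:
        raise InvalidParameterError("het_hom_ratio must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    hc_regions = {
        contig: merge_intervals(ivals) for contig, ivals in (hc_regions or {}).items()
    }
    calls_by_contig: dict[str, list[SnvCall]] = {}
    for call in snv_calls or ():
        calls_by_contig.setdefault(call.contig, []).append(call)

    p_site = lc_density / 1000.0
    p_hom = 1.0 / (1.0 + het_hom_ratio)
    haplotypes: dict[str, tuple[str, str]] = {}
    rows: list[tuple[str, int, str, str, str]] = []

    for contig, seq in reference.items():
        seq = seq.upper()
        length = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hap1 = arr.copy()
        hap2 = arr.copy()
        hc_mask = _region_mask(length, hc_regions.get(contig, ()))
        taken = np.zeros(length, dtype=bool)

        # supplied calls first: authoritative inside high-confidence regions
        for call in sorted(calls_by_contig.get(contig, ()), key=lambda c: c.pos):
            if not (0 <= call.pos < length):
                raise InvalidParameterError(
                    f"call at {contig}:{call.pos} outside contig bounds"
                )
            if hc_regions.get(contig) and not hc_mask[call.pos]:
                continue  # calls restricted to high-confidence regions
            if seq[call.pos] != call.ref.upper():
                raise ConsistencyError(
                    f"call ref {call.ref!r} does not match reference base "
                    f"{seq[call.pos]!r} at {contig}:{call.pos}"
                )
            if taken[call.pos]:
                continue
            zyg = call.zygosity
            if zyg is None:
                zyg = HET_HAP1 if rng.random() < 0.5 else HET_HAP2
            alt = ord(call.alt.upper())
            if zyg in (HOM, HET_HAP1):
                hap1[call.pos] = alt
            if zyg in (HOM, HET_HAP2):
                hap2[call.pos] = alt
            taken[call.pos] = True
            rows.append((contig, call.pos, call.ref.upper(), call.alt.upper(), zyg))

        # random low-confidence SNVs outside hc regions and call positions
        if p_site > 0:
            eligible = ~hc_mask & ~taken & (arr != _N)
            hits = np.nonzero(eligible & (rng.random(length) < p_site))[0]
            if hits.size:
                hom = rng.random(hits.size) < p_hom
                het_hap = rng.integers(1, 3, size=hits.size)
                alt_idx = rng.integers(0, 3, size=hits.size)
                for pos, is_hom, hap_k, ai in zip(hits, hom, het_hap, alt_idx):
                    ref_base = seq[pos]
                    alt_base = _ALT_CHOICES[ref_base][ai]
                    if is_hom:
                        zyg = HOM
                        hap1[pos] = hap2[pos] = ord(alt_base)
                    elif hap_k == 1:
                        zyg = HET_HAP1
                        hap1[pos] = ord(alt_base)
                    else:
                        zyg = HET_HAP2
                        hap2[pos] = ord(alt_base)
                    rows.append((contig, int(pos), ref_base, alt_base, zyg))

        haplotypes[contig] = (hap1.tobytes().decode(), hap2.tobytes().decode())

    table = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "zygosity"]
    ).sort_values(["contig", "pos"], ignore_index=True)
    return DiploidTemplate(
        haplotypes=haplotypes,
        snv_table=table,
        ref_lengths={contig: len(seq) for contig, seq in reference.items()},
    )
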