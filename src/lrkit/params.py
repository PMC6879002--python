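"""Library-design parameter algebra for Linked-Read experiments.

A Linked-Read (10x Chromium style) library is described by a small set of
interdependent quantities:

``C``
    total sequence coverage of the genome (fold),
``C_F``
    physical coverage: summed long-fragment length per haploid genome
    length (fold),
``C_R``
    mean short-read coverage within a single long fragment (fold),
``N_F/P``
    mean number of long fragments sharing one barcoded partition,
``muFL`` / ``WmuFL``
    unweighted and length-weighted mean fragment length (bp).

They obey the identity ``C = C_F * C_R``: every genomic position is touched
by ``C_F`` molecules on average, and each molecule is read to depth ``C_R``.
This module holds the identity, fragment-length summaries, design-point
validation, and the flat ``key = value`` config format shared by the
simulator, the molecule-inference code and the command line.

Coverage conventions used throughout the package:

* ``C_F`` is accounted against the *haploid* reference length, with
  simulated molecules split evenly between the two haplotypes.
* ``C_R`` counts *genomic* bases only.  The forward read of every pair
  donates its first 16 bases to the partition barcode and the next 7 to an
  ``N`` spacer, so a 2 x 150 bp pair carries ``127 + 150 = 277`` genomic
  bases.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BARCODE_LEN",
    "N_SPACER",
    "MASKED_PREFIX",
    "InvalidParameterError",
    "EmptyInputError",
    "ConsistencyError",
    "LibraryParams",
    "FragmentLengthSummary",
    "total_coverage",
    "weighted_mean_fragment_length",
    "summarize_lengths",
    "genomic_bases_per_pair",
    "load_config",
    "save_config",
    "derive_seed",
    "stage_rng",
]

#: bases of partition barcode at the start of every forward read
BARCODE_LEN = 16
#: ``N`` spacer bases between the barcode and genomic sequence
N_SPACER = 7
#: total non-genomic prefix on the forward read
MASKED_PREFIX = BARCODE_LEN + N_SPACER

#: practical ceiling on distinct barcodes supported by downstream assemblers
MAX_BARCODES = 4_800_000


class InvalidParameterError(ValueError):
    """A design parameter is outside its valid domain."""


class EmptyInputError(ValueError):
    """An operation requiring a nonempty collection received an empty one."""


class ConsistencyError(ValueError):
    """Inputs contradict each other (e.g. C given but != C_F * C_R)."""


# ---------------------------------------------------------------------------
# coverage identity
# ---------------------------------------------------------------------------

def total_coverage(c_f: float, c_r: float) -> float:
    """Total sequence coverage ``C = C_F * C_R``.

    Parameters
    ----------
    c_f : physical (long-fragment) coverage of the haploid genome, fold.
    c_r : mean read coverage per fragment, fold.
    """
    if not (c_f > 0 and c_r > 0):
        raise InvalidParameterError(
            f"coverages must be positive, got C_F={c_f!r}, C_R={c_r!r}"
        )
    return c_f * c_r


def genomic_bases_per_pair(read_len: int = 150) -> int:
    """Genomic bases contributed by one read pair.

    The forward read's first ``MASKED_PREFIX`` (23) bases are barcode and
    spacer, leaving ``read_len - 23`` genomic bases; the reverse read is
    fully genomic.
    """
    if read_len <= MASKED_PREFIX:
        raise InvalidParameterError(
            f"read_len must exceed the {MASKED_PREFIX} masked prefix bases"
        )
    return 2 * read_len - MASKED_PREFIX


# ---------------------------------------------------------------------------
# fragment-length summaries
# ---------------------------------------------------------------------------

def weighted_mean_fragment_length(lengths: Sequence[float]) -> float:
    """Length-weighted mean fragment length, ``sum(L^2) / sum(L)``.

    This weights each molecule by the number of bases it contributes, the
    statistic usually quoted as *WmuFL*.  For exponentially distributed
    lengths of mean ``mu`` it converges to ``2 * mu``.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("no fragment lengths supplied")
    if np.any(arr <= 0):
        raise InvalidParameterError("fragment lengths must be positive")
    return float(np.sum(arr * arr) / np.sum(arr))


@dataclass(frozen=True)
class FragmentLengthSummary:
    """Summary statistics of a set of long-fragment lengths."""

    mu_FL: float
    W_mu_FL: float
    n_fragments: int
    total_bases: float
    _lengths: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        # weighted mean dominates the unweighted mean for nonneg lengths
        if self.W_mu_FL < self.mu_FL - 1e-9 * self.mu_FL:
            raise ConsistencyError("W_mu_FL < mu_FL is impossible")

    def distribution(self, n_bins: int = 100) -> pd.DataFrame:
        """Binned PDF/CDF tables of the length distribution.

        Returns one row per bin with the probability density of unweighted
        lengths, its CDF and reverse CDF, and the reverse CDF of
        length-weighted mass (the fraction of all bases residing in
        fragments at least as long as the bin start).
        """
        if self._lengths is None:
            raise EmptyInputError("summary was built without raw lengths")
        counts, edges = np.histogram(self._lengths, bins=n_bins)
        pdf = counts / counts.sum()
        cdf = np.cumsum(pdf)
        wmass, _ = np.histogram(self._lengths, bins=edges, weights=self._lengths)
        wmass = wmass / wmass.sum()
        rev = lambda a: a[::-1].cumsum()[::-1]  # noqa: E731
        return pd.DataFrame(
            {
                "bin_left": edges[:-1],
                "bin_right": edges[1:],
                "pdf": pdf,
                "cdf": cdf,
                "rcdf": rev(pdf),
                "weighted_rcdf": rev(wmass),
            }
        )


def summarize_lengths(lengths: Sequence[float]) -> FragmentLengthSummary:
    """Aggregate fragment lengths into a :class:`FragmentLengthSummary`."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("no fragment lengths supplied")
    return FragmentLengthSummary(
        mu_FL=float(arr.mean()),
        W_mu_FL=weighted_mean_fragment_length(arr),
        n_fragments=int(arr.size),
        total_bases=float(arr.sum()),
        _lengths=arr,
    )


# ---------------------------------------------------------------------------
# design points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryParams:
    """One Linked-Read experiment design point.

    Exactly two of ``c``, ``c_f``, ``c_r`` are free; the third follows from
    ``C = C_F * C_R``.  Use :meth:`resolve` to construct from any valid pair
    (or a consistent triple).
    """

    c: float
    c_f: float
    c_r: float
    n_fp: float = 10.0
    mu_fl: float = 37_000.0
    read_len: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    barcode_len: int = BARCODE_LEN
    n_spacer: int = N_SPACER
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "c_f", "c_r", "n_fp", "mu_fl"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0 <= self.error_rate < 1):
            raise InvalidParameterError("error_rate must lie in [0, 1)")
        if self.insert_mean < 2 * self.read_len:
            raise InvalidParameterError(
                "insert_mean must be at least twice the read length"
            )
        if not math.isclose(self.c, self.c_f * self.c_r, rel_tol=1e-9):
            raise ConsistencyError(
                f"C={self.c} inconsistent with C_F*C_R={self.c_f * self.c_r}"
            )

    @classmethod
    def resolve(
        cls,
        c: float | None = None,
        c_f: float | None = None,
        c_r: float | None = None,
        **kwargs,
    ) -> "LibraryParams":
        """Build a design point from any two of ``{C, C_F, C_R}``.

        A consistent triple is accepted; a contradictory one, or fewer than
        two values, is an error.
        """
        given = sum(v is not None for v in (c, c_f, c_r))
        if given < 2:
            raise InvalidParameterError(
                "at least two of C, C_F, C_R must be specified"
            )
        if c is None:
            c = total_coverage(c_f, c_r)
        elif c_f is None:
            if not c_r > 0:
                raise InvalidParameterError("C_R must be > 0")
            c_f = c / c_r
        elif c_r is None:
            if not c_f > 0:
                raise InvalidParameterError("C_F must be > 0")
            c_r = c / c_f
        return cls(c=c, c_f=c_f, c_r=c_r, **kwargs)

    @property
    def genomic_bases_per_pair(self) -> int:
        return 2 * self.read_len - self.barcode_len - self.n_spacer

    def with_seed(self, seed: int) -> "LibraryParams":
        return replace(self, seed=seed)

    def to_config(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_config(cls, cfg: Mapping[str, object]) -> "LibraryParams":
        known = {f.name for f in fields(cls)}
        vals = {k: v for k, v in cfg.items() if k in known}
        c = vals.pop("c", None)
        c_f = vals.pop("c_f", None)
        c_r = vals.pop("c_r", None)
        return cls.resolve(c=c, c_f=c_f, c_r=c_r, **vals)


# ---------------------------------------------------------------------------
# flat key = value config files
# ---------------------------------------------------------------------------

def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def load_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config file (``#`` starts a comment)."""
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidParameterError(f"malformed config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = _parse_scalar(value)
    return cfg


def save_config(cfg: Mapping[str, object], path: str | Path) -> None:
    """Write a mapping as a flat ``key = value`` config file."""
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# seeded reproducibility
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from a master seed and a stage name.

    Each pipeline stage draws from its own stream so that changing one
    stage's parameters does not perturb another stage's randomness.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A NumPy generator seeded for one named pipeline stage."""
    return np.random.default_rng(derive_seed(master_seed, stage))
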