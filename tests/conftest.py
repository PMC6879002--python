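"""Shared fixtures: synthetic genomes and simulated libraries.

All simulation fixtures are session-scoped and seeded, so the suite is
deterministic and each library is generated once.
"""

from __future__ import annotations

from types import SimpleNamespace

import pandas as pd
import pytest

from lrkit import (
    LibraryParams,
    SyntheticReferenceSpec,
    allocate_partitions,
    build_template,
    generate_reads,
    generate_reference,
    shear_fragments,
)


def placements_of(records, hap_aware: bool = True) -> pd.DataFrame:
    """Pair placements from in-memory read records."""
    rows = [
        (
            r.read_id,
            r.barcode,
            f"{r.contig}_hap{r.haplotype}" if hap_aware else r.contig,
            r.r1_start,
            r.r1_start + r.insert_len,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "barcode", "contig", "leftmost", "rightmost"]
    )


def _simulate(contig_len: int, c_f: float, c_r: float, n_fp: float, seed: int,
              mu_fl: float = 37_000.0, min_len: int = 1000):
    ref, _ = generate_reference(
        SyntheticReferenceSpec(contig_len=contig_len, gc_content=0.41, seed=seed)
    )
    template = build_template(ref, seed=seed + 1)
    fragments = shear_fragments(
        template, mu_fl=mu_fl, c_f=c_f, min_len=min_len, seed=seed + 2
    )
    partitions = allocate_partitions(fragments, n_fp=n_fp, seed=seed + 3)
    counters: dict = {}
    records = list(
        generate_reads(
            template, fragments, partitions, c_r=c_r, seed=seed + 4,
            counters=counters,
        )
    )
    return SimpleNamespace(
        template=template,
        fragments=fragments,
        partitions=partitions,
        records=records,
        counters=counters,
        params=LibraryParams.resolve(c_f=c_f, c_r=c_r, n_fp=n_fp, mu_fl=mu_fl),
    )


@pytest.fixture(scope="session")
def template_1mb():
    ref, _ = generate_reference(
        SyntheticReferenceSpec(contig_len=1_000_000, gc_content=0.41, seed=11)
    )
    return build_template(ref, seed=11)


@pytest.fixture(scope="session")
def midsim():
    """A moderate library: 500 kb genome, C_F = 50, C_R = 0.2, N_F/P = 10."""
    return _simulate(contig_len=500_000, c_f=50.0, c_r=0.2, n_fp=10.0, seed=101)


@pytest.fixture(scope="session")
def midsim_placements(midsim):
    return placements_of(midsim.records)


@pytest.fixture(scope="session")
def lowcollision_run():
    """Sparse partitions (N_F/P = 2) on 2 Mb: molecule chains rarely collide."""
    return _simulate(contig_len=2_000_000, c_f=30.0, c_r=0.2, n_fp=2.0, seed=202)


@pytest.fixture(scope="session")
def recovery_run():
    """The whole-pipeline parameter-recovery design point on 2 Mb."""
    return _simulate(contig_len=2_000_000, c_f=200.0, c_r=0.2, n_fp=10.0, seed=7)
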