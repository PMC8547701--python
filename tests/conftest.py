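"""Shared fixtures: random nested annotations and a per-base sweep oracle."""

from __future__ import annotations

import numpy as np
import pytest

from te_ecology.annotation import TECopy

SUPERFAMILY_CYCLE = ["RLG", "RLC", "DTA", "DHH", "DTT", "RIL", "RST"]


def make_random_annotation(
    rng: np.random.Generator,
    genome_len: int = 50_000,
    n_copies: int = 30,
    max_depth: int = 4,
    nesting_probability: float = 0.4,
) -> list[TECopy]:
    """Random nested TE annotation; creation order is arrival order and is
    recoverable from the nesting topology (only nesting creates overlaps)."""
    copies: list[TECopy] = []
    depth = {}
    for i in range(n_copies):
        length = int(rng.integers(200, 4000))
        parent = None
        placed = None
        if copies and rng.random() < nesting_probability:
            hosts = [c for c in copies if c.span_bp >= length + 2 and depth[c.copy_id] < max_depth - 1]
            rng.shuffle(hosts)
            for host in hosts:
                start = int(rng.integers(host.start + 1, host.end - length))
                end = start + length
                # accept only if every overlapping earlier copy fully
                # contains the child (an ancestor); partial overlap or the
                # child swallowing an earlier copy would leave arrival
                # order unrecoverable from topology
                ok = True
                for c in copies:
                    if c.copy_id == host.copy_id or c.chrom != host.chrom:
                        continue
                    if c.start < end and start < c.end:
                        # must be an ancestor fully containing, or fully outside
                        if not (c.start <= start and end <= c.end):
                            ok = False
                            break
                if ok:
                    placed = (host.chrom, start)
                    parent = host.copy_id
                    break
        if placed is None:
            for _ in range(200):
                start = int(rng.integers(0, genome_len - length))
                end = start + length
                if all(c.end <= start or end <= c.start for c in copies):
                    placed = ("chr1", start)
                    parent = None
                    break
            if placed is None:
                continue
        sf = SUPERFAMILY_CYCLE[i % len(SUPERFAMILY_CYCLE)]
        cid = f"te{i:04d}"
        copies.append(
            TECopy(copy_id=cid, family_id=f"{sf}{(i % 9) + 1:05d}", superfamily=sf,
                   chrom=placed[0], start=placed[1], end=placed[1] + length,
                   parent_te=parent)
        )
        depth[cid] = 0 if parent is None else depth[parent] + 1
    return copies


def per_base_ownership(copies: list[TECopy], genome_len: int = 50_000) -> dict[str, list[tuple[int, int]]]:
    """Brute-force oracle: paint each base in creation (arrival) order, then
    read maximal runs per owner."""
    arr = np.full(genome_len, -1, dtype=int)
    ids = [c.copy_id for c in copies]
    for i, c in enumerate(copies):
        arr[c.start : c.end] = i
    segments: dict[str, list[tuple[int, int]]] = {cid: [] for cid in ids}
    run_owner, run_start = -1, 0
    for pos in range(genome_len + 1):
        owner = arr[pos] if pos < genome_len else -1
        if owner != run_owner:
            if run_owner >= 0:
                segments[ids[run_owner]].append((run_start, pos))
            run_owner, run_start = owner, pos
    return segments


@pytest.fixture
def annotation_factory():
    return make_random_annotation


@pytest.fixture
def ownership_oracle():
    return per_base_ownership
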