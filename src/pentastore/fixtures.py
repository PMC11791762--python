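"""Reproducible synthetic inputs: random files and read sets.

Stands in for the real artefacts the system stores and sequences: a
random byte file of exact requested size plays the stored document, and
:func:`make_store_reads` builds the full chain — encode, plan assembly,
simulate barcoded noisy reads — in one call for pipeline experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .adaptors import design_adaptors
from .assembly import AssemblyPlan, plan_groups
from .codec import RotationTable, default_table
from .packets import Oligo, StoreManifest, encode_store
from .readsim import ReadRecord, ReadSimConfig, make_read_set

__all__ = ["random_file", "StoreFixture", "make_store_reads"]

DEFAULT_BARCODES = ("TTAACCGGATGCTAAG", "CTTAGCATCCGGTTAA")


@lru_cache(maxsize=1)
def _default_adaptor_pool() -> tuple[str, ...]:
    return tuple(design_adaptors())


def random_file(n_bytes: int, seed: int = 0) -> bytes:
    """Uniformly random bytes of exact length, deterministic under seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=n_bytes, dtype=np.uint8).tobytes()


@dataclass
class StoreFixture:
    """Everything a pipeline experiment needs, generated from one seed."""

    data: bytes
    oligos: list[Oligo]
    manifest: StoreManifest
    plan: AssemblyPlan
    fragments: list[str]  # assembled subfragment sequences (letters incl. M)
    adaptors: tuple[str, ...]
    barcodes: tuple[str, str]
    reads: list[ReadRecord]


def make_store_reads(
    n_bytes: int = 132,
    cfg: ReadSimConfig | None = None,
    seed: int = 0,
    group_size: int | None = None,
    table: RotationTable | None = None,
) -> StoreFixture:
    """Encode a random file, assemble fragments, and simulate reads of them.

    ``group_size`` defaults to the whole oligo count (one group), so any
    file size works without padding; pass 27 for the canonical grouping.
    Each assembled subfragment is sequenced at ``cfg.depth``.
    """
    cfg = cfg or ReadSimConfig(
        barcode_left=DEFAULT_BARCODES[0], barcode_right=DEFAULT_BARCODES[1]
    )
    table = table or default_table()
    data = random_file(n_bytes, seed)
    oligos, manifest = encode_store(data, table)
    gs = group_size or len(oligos)
    adaptor_set = _default_adaptor_pool()
    if gs > len(adaptor_set):
        raise ValueError(f"group size {gs} exceeds the {len(adaptor_set)}-adaptor pool")
    plan = plan_groups(oligos, list(adaptor_set), group_size=gs)
    fragments = []
    for sub1, sub2 in plan.fragment_sequences():
        if sub1:
            fragments.append(sub1)
        if sub2:
            fragments.append(sub2)
    reads = make_read_set(fragments, cfg, seed)
    return StoreFixture(
        data,
        oligos,
        manifest,
        plan,
        fragments,
        tuple(adaptor_set)[:gs],
        (cfg.barcode_left, cfg.barcode_right),
        reads,
    )
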