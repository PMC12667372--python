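"""Block-compressed haplotype reference panels.

A phased reference panel is a binary allele matrix (haplotypes x sites).
Following the M3VCF idea used by fast imputation servers, the site axis is
tiled into short contiguous blocks and each block keeps only the *unique*
haplotype rows it contains, plus a per-haplotype map back to those rows.
Real panels are highly redundant locally, so the unique-row count per block
is typically far below the haplotype count -- every downstream stage
(prefix-tree PBWT, neighbour search) then works on unique rows only.

Blocks are grown greedily site by site under two caps: a maximum width and a
maximum number of unique rows.  Blocks tile the site range exactly and do
not overlap; continuity of suffix matches across block boundaries is handled
explicitly by the compressed-PBWT layer, not by overlapping marker columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "HaplotypePanel",
    "CompressedBlock",
    "CompressedPanel",
    "partition_blocks",
    "compress_block",
    "compress_panel",
    "decompress",
    "write_compressed_text",
    "read_compressed_text",
    "DEFAULT_MAX_WIDTH",
    "DEFAULT_MAX_UNIQUES",
]

DEFAULT_MAX_WIDTH = 32
DEFAULT_MAX_UNIQUES = 256


@dataclass
class HaplotypePanel:
    """Uncompressed phased panel: one row per haplotype (not per sample)."""

    alleles: np.ndarray  # (n_hap, n_sites) of {0,1}
    site_ids: list = field(default_factory=list)  # (chrom, pos, ref, alt)
    positions: np.ndarray | None = None  # 1-based physical positions

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel must be biallelic: alleles in {0, 1}")
        if self.positions is None:
            self.positions = np.arange(1, self.n_sites + 1, dtype=np.int64)
        else:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
        if not self.site_ids:
            self.site_ids = [("1", int(p), "A", "G") for p in self.positions]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass
class CompressedBlock:
    """Unique haplotype rows over a half-open site range ``[start, end)``."""

    start: int
    end: int
    uniques: np.ndarray  # (n_unique, end - start)
    index_map: np.ndarray  # (n_hap,) -> row of uniques

    def __post_init__(self):
        self.uniques = np.asarray(self.uniques, dtype=np.int8)
        self.index_map = np.asarray(self.index_map, dtype=np.int64)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def n_unique(self) -> int:
        return self.uniques.shape[0]


@dataclass
class CompressedPanel:
    blocks: list  # ordered CompressedBlock tiling [0, n_sites)
    n_hap: int
    n_sites: int
    site_ids: list = field(default_factory=list)
    positions: np.ndarray | None = None


def partition_blocks(
    panel: HaplotypePanel,
    max_width: int = DEFAULT_MAX_WIDTH,
    max_uniques: int = DEFAULT_MAX_UNIQUES,
) -> list[tuple[int, int]]:
    """Greedy tiling of the site range under the width and unique-row caps.

    Each block grows site by site until adding the next site would push its
    width past ``max_width`` or its unique-row count past ``max_uniques``.
    The first site of a block is always accepted so progress is guaranteed.
    """
    if max_width < 1 or max_uniques < 1:
        raise ValueError("max_width and max_uniques must be >= 1")
    if panel.n_hap == 0 or panel.n_sites == 0:
        raise ValueError("empty panel")
    bounds = []
    start = 0
    ids = np.zeros(panel.n_hap, dtype=np.int64)
    width = 0
    for j in range(panel.n_sites):
        merged = ids * 2 + panel.alleles[:, j]
        _, new_ids = np.unique(merged, return_inverse=True)
        n_u = int(new_ids.max()) + 1
        if width > 0 and (width + 1 > max_width or n_u > max_uniques):
            bounds.append((start, j))
            start = j
            _, ids = np.unique(panel.alleles[:, j], return_inverse=True)
            ids = ids.astype(np.int64)
            width = 1
        else:
            ids = new_ids.astype(np.int64)
            width += 1
    bounds.append((start, panel.n_sites))
    return bounds


def compress_block(panel: HaplotypePanel, start: int, end: int) -> CompressedBlock:
    """Deduplicate haplotype rows over ``[start, end)``.

    Unique rows are ordered by first appearance so the output is a
    deterministic function of the panel.
    """
    if not 0 <= start < end <= panel.n_sites:
        raise ValueError(f"invalid block range [{start}, {end})")
    rows = panel.alleles[:, start:end]
    _, first_idx, inverse = np.unique(
        rows, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return CompressedBlock(
        start=start,
        end=end,
        uniques=rows[np.sort(first_idx)],
        index_map=rank[inverse],
    )


def compress_panel(
    panel: HaplotypePanel,
    max_width: int = DEFAULT_MAX_WIDTH,
    max_uniques: int = DEFAULT_MAX_UNIQUES,
) -> CompressedPanel:
    bounds = partition_blocks(panel, max_width, max_uniques)
    blocks = [compress_block(panel, s, e) for s, e in bounds]
    return CompressedPanel(
        blocks=blocks,
        n_hap=panel.n_hap,
        n_sites=panel.n_sites,
        site_ids=list(panel.site_ids),
        positions=None if panel.positions is None else panel.positions.copy(),
    )


def decompress(cp: CompressedPanel) -> HaplotypePanel:
    """Exact reconstruction of the original allele matrix."""
    if not cp.blocks:
        raise ValueError("compressed panel has no blocks")
    parts = []
    for blk in cp.blocks:
        if blk.index_map.shape[0] != cp.n_hap:
            raise ValueError("index_map length inconsistent with panel")
        parts.append(blk.uniques[blk.index_map])
    alleles = np.concatenate(parts, axis=1)
    if alleles.shape[1] != cp.n_sites:
        raise ValueError("blocks do not tile the site range")
    return HaplotypePanel(
        alleles=alleles,
        site_ids=list(cp.site_ids),
        positions=None if cp.positions is None else cp.positions.copy(),
    )


# ---------------------------------------------------------------------------
# plain-text block format
# ---------------------------------------------------------------------------
# A self-defined dialect (M3VCF has no public formal spec):
#   line 1:  #obliphase-cpanel 1 <n_hap> <n_sites> <n_blocks>
#   one line per site:  ##site <chrom> <pos> <ref> <alt>
#   per block:  #block <start> <end> <n_unique>
#               n_unique lines of 0/1 strings (the unique rows)
#               one line of space-separated index_map entries

def write_compressed_text(cp: CompressedPanel, path_or_buf) -> None:
    buf = io.StringIO()
    buf.write(f"#obliphase-cpanel 1 {cp.n_hap} {cp.n_sites} {len(cp.blocks)}\n")
    for chrom, pos, ref, alt in cp.site_ids:
        buf.write(f"##site {chrom} {pos} {ref} {alt}\n")
    for blk in cp.blocks:
        buf.write(f"#block {blk.start} {blk.end} {blk.n_unique}\n")
        for row in blk.uniques:
            buf.write("".join("1" if a else "0" for a in row) + "\n")
        buf.write(" ".join(str(int(i)) for i in blk.index_map) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_compressed_text(path_or_buf) -> CompressedPanel:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split()
    if header[0] != "#obliphase-cpanel" or header[1] != "1":
        raise ValueError("not an obliphase compressed-panel file")
    n_hap, n_sites, n_blocks = (int(x) for x in header[2:5])
    site_ids = []
    k = 1
    while k < len(lines) and lines[k].startswith("##site"):
        _, chrom, pos, ref, alt = lines[k].split()
        site_ids.append((chrom, int(pos), ref, alt))
        k += 1
    blocks = []
    for _ in range(n_blocks):
        tag, start, end, n_unique = lines[k].split()
        if tag != "#block":
            raise ValueError("malformed block header")
        start, end, n_unique = int(start), int(end), int(n_unique)
        k += 1
        uniques = np.array(
            [[int(c) for c in lines[k + r]] for r in range(n_unique)], dtype=np.int8
        )
        k += n_unique
        index_map = np.array([int(x) for x in lines[k].split()], dtype=np.int64)
        k += 1
        blocks.append(CompressedBlock(start, end, uniques, index_map))
    positions = np.array([s[1] for s in site_ids], dtype=np.int64) if site_ids else None
    return CompressedPanel(blocks, n_hap, n_sites, site_ids, positions)
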