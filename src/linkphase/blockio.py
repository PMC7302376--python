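"""Text output format for phased haplotype blocks.

Each block starts with a header line giving the number of phased sites,
the number of supporting fragments and the block MEC, followed by one row
per variant: 1-based variant index, genomic position, K allele columns
(``-`` for an uncovered position) and K quality columns holding the number
of fragment calls matching the reported allele.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GAP, HaplotypeBlock


def write_blocks(
    blocks: Sequence[HaplotypeBlock],
    positions: np.ndarray,
    path: str | Path,
) -> None:
    """``positions`` maps 1-based variant index -> genomic bp."""
    positions = np.asarray(positions)
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"BLOCK len {b.n_sites} reads {b.n_fragments} MEC {b.mec}\n")
            for j, idx in enumerate(b.variant_indices):
                alleles = [
                    "-" if a == GAP else str(a) for a in b.haplotypes[:, j]
                ]
                support = [str(s) for s in b.support[:, j]]
                fh.write(
                    "\t".join(
                        [str(idx), str(positions[idx - 1])]
                        + alleles
                        + support
                    )
                    + "\n"
                )
            fh.write("****\n")


def read_blocks(path: str | Path, ploidy: int) -> list[HaplotypeBlock]:
    blocks: list[HaplotypeBlock] = []
    indices: list[int] = []
    haps: list[list[int]] = []
    supp: list[list[int]] = []
    header: tuple[int, int] | None = None

    def flush() -> None:
        nonlocal indices, haps, supp, header
        if not indices:
            return
        blocks.append(
            HaplotypeBlock(
                variant_indices=tuple(indices),
                haplotypes=np.asarray(haps, dtype=np.int64).T,
                support=np.asarray(supp, dtype=np.int64).T,
                mec=header[1] if header else 0,
                n_fragments=header[0] if header else 0,
            )
        )
        indices, haps, supp, header = [], [], [], None

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("BLOCK"):
                flush()
                toks = line.split()
                header = (int(toks[4]), int(toks[6]))
                continue
            if line.startswith("****"):
                flush()
                continue
            toks = line.split("\t")
            indices.append(int(toks[0]))
            alleles = toks[2 : 2 + ploidy]
            haps.append([GAP if a == "-" else int(a) for a in alleles])
            supp.append([int(s) for s in toks[2 + ploidy : 2 + 2 * ploidy]])
    flush()
    return blocks
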