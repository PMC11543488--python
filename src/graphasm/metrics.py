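"""Reference-based assembly evaluation on synthetic genomes.

Contigs are aligned to the known reference by exact k-mer anchoring: shared
k-mers are grouped into collinear runs (blocks) on a common diagonal, and
each discordant junction between consecutive blocks of a contig counts as a
misassembly.  From the block lengths the usual contiguity statistics are
derived: NA50 (denominator = total assembly length), NGA50 (denominator =
reference length) and genome fraction (percent of reference bases covered
by at least one block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ContigSet
from .simulate import SyntheticGenome


@dataclass
class AlignedBlock:
    contig_name: str
    contig_start: int
    contig_end: int
    ref_start: int
    ref_end: int

    @property
    def length(self) -> int:
        return self.contig_end - self.contig_start


@dataclass
class AssemblyReport:
    contig_count: int
    largest_contig: int
    genome_fraction: float
    na50: int
    nga50: int
    misassembly_count: int
    total_length: int = 0
    blocks: list[AlignedBlock] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "contigs": self.contig_count,
            "largest_contig": self.largest_contig,
            "total_length": self.total_length,
            "genome_fraction": round(self.genome_fraction, 3),
            "na50": self.na50,
            "nga50": self.nga50,
            "misassemblies": self.misassembly_count,
        }

    def __str__(self) -> str:
        lines = [f"{k:>16}: {v}" for k, v in self.as_dict().items()]
        return "\n".join(lines)


def _kmer_index(reference: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)
    return index


def aligned_blocks(
    contigs: ContigSet,
    reference: SyntheticGenome,
    k: int = 31,
    stride: int = 8,
    band: int = 100,
) -> list[AlignedBlock]:
    """Maximal collinear anchor runs between each contig and the reference.

    Contig k-mers sampled every ``stride`` bases are looked up in the
    reference; anchors whose diagonal (ref position - contig position) stays
    within ``band`` and whose positions advance monotonically are merged
    into one block.  Repeat-induced multi-mapping k-mers contribute the
    anchor continuing the current diagonal when one exists.
    """
    ref = reference.sequence
    index = _kmer_index(ref, k)
    blocks: list[AlignedBlock] = []
    for contig in contigs.contigs:
        seq = contig.sequence
        if len(seq) < k:
            continue
        anchors: list[tuple[int, int]] = []  # (contig_pos, ref_pos)
        positions = list(range(0, len(seq) - k + 1, stride))
        if positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        prev_diag = None
        for cpos in positions:
            hits = index.get(seq[cpos : cpos + k])
            if not hits:
                continue
            if prev_diag is not None:
                on_diag = [r for r in hits if abs((r - cpos) - prev_diag) <= band]
                rpos = on_diag[0] if on_diag else hits[0]
            else:
                rpos = hits[0]
            anchors.append((cpos, rpos))
            prev_diag = rpos - cpos
        # merge anchors into diagonal-consistent monotone blocks
        current: list[tuple[int, int]] = []
        for anchor in anchors:
            if not current:
                current = [anchor]
                continue
            lc, lr = current[-1]
            cpos, rpos = anchor
            same_diag = abs((rpos - cpos) - (lr - lc)) <= band
            if same_diag and rpos >= lr:
                current.append(anchor)
            else:
                blocks.append(_block_from(current, contig.name, k))
                current = [anchor]
        if current:
            blocks.append(_block_from(current, contig.name, k))
    return blocks


def _block_from(anchors: list[tuple[int, int]], name: str, k: int) -> AlignedBlock:
    return AlignedBlock(
        name,
        anchors[0][0],
        anchors[-1][0] + k,
        min(a[1] for a in anchors),
        max(a[1] for a in anchors) + k,
    )


def count_misassemblies(blocks: list[AlignedBlock], junction_distance: int = 1000) -> int:
    """Discordant junctions between consecutive blocks of the same contig.

    Consecutive blocks whose diagonals differ by more than
    ``junction_distance`` (or that step backward on the reference) count one
    misassembly each.
    """
    by_contig: dict[str, list[AlignedBlock]] = {}
    for block in blocks:
        by_contig.setdefault(block.contig_name, []).append(block)
    count = 0
    for blist in by_contig.values():
        blist.sort(key=lambda b: b.contig_start)
        for left, right in zip(blist[:-1], blist[1:]):
            diag_l = left.ref_end - left.contig_end
            diag_r = right.ref_start - right.contig_start
            if abs(diag_r - diag_l) > junction_distance or right.ref_start < left.ref_start:
                count += 1
    return count


def nx_statistic(block_lengths, denominator: int) -> int:
    """Length of the shortest block at which sorted blocks reach half the denominator.

    Returns 0 when the blocks sum to less than half the denominator.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    lengths = sorted((int(x) for x in block_lengths), reverse=True)
    half = denominator / 2
    cumulative = 0
    for length in lengths:
        cumulative += length
        if cumulative >= half:
            return length
    return 0


def genome_fraction(blocks: list[AlignedBlock], reference_length: int) -> float:
    """Percent of reference bases covered by the union of block intervals."""
    intervals = sorted((b.ref_start, b.ref_end) for b in blocks)
    covered = 0
    cur_start, cur_end = None, None
    for start, end in intervals:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return 100.0 * covered / reference_length


def evaluate_assembly(
    contigs: ContigSet,
    reference: SyntheticGenome,
    k: int = 31,
    junction_distance: int = 1000,
) -> AssemblyReport:
    """Full report: contiguity and accuracy of a contig set vs the reference."""
    blocks = aligned_blocks(contigs, reference, k=k)
    lengths = contigs.lengths()
    total = sum(lengths)
    block_lengths = [b.length for b in blocks]
    return AssemblyReport(
        contig_count=len(contigs),
        largest_contig=max(lengths, default=0),
        genome_fraction=genome_fraction(blocks, len(reference)) if blocks else 0.0,
        na50=nx_statistic(block_lengths, total) if total else 0,
        nga50=nx_statistic(block_lengths, len(reference)),
        misassembly_count=count_misassemblies(blocks, junction_distance),
        total_length=total,
        blocks=blocks,
    )


def report_to_csv(report: AssemblyReport, path) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        data = report.as_dict()
        writer.writerow(data.keys())
        writer.writerow(data.values())
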