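"""Synthetic genome and HiFi-like read simulation with known coordinates.

Generates a random genome with controllable exact-repeat content, samples
long high-accuracy reads from it while recording each read's true interval
and strand, and builds the overlap graph directly from those coordinates.
Because every read carries its ground truth, graph labeling, model training
and assembly evaluation all run hermetically, with no external aligner or
assembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import AssemblyGraph

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RepeatAnnotation:
    """An exact duplicated interval: genome[start:end] == genome[copy_of:copy_of+(end-start)]."""

    start: int
    end: int
    copy_of: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticGenome:
    sequence: str
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedRead:
    """A read plus its true source interval (0-based, half-open) and strand."""

    read_id: str
    sequence: str
    start: int
    end: int
    strand: str = "+"

    @property
    def true_length(self) -> int:
        return self.end - self.start


def generate_genome(
    length: int,
    repeat_fraction: float = 0.3,
    repeat_unit_length: int = 2_000,
    seed: int = 0,
    repeat_copies: int = 10,
) -> SyntheticGenome:
    """Uniform-random genome with multi-copy exact repeat families.

    Repeat families of ``repeat_copies`` identical units of
    ``repeat_unit_length`` bp are planted (one source interval, the others
    overwritten with its content) at non-overlapping positions until repeat
    copies cover about ``repeat_fraction`` of the genome — emulating the
    dispersed high-identity families (transposons, segmental duplications)
    that make real assembly graphs ambiguous.  Deterministic for a given
    seed.
    """
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    if repeat_copies < 2:
        raise ValueError("repeat_copies must be >= 2")
    if repeat_fraction > 0 and length < 10 * repeat_unit_length:
        raise ValueError(
            "genome length must be >= 10 * repeat_unit_length to place repeats"
        )
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    annotations: list[RepeatAnnotation] = []
    n_copies_total = int(round(repeat_fraction * length / repeat_unit_length))
    # Occupied intervals (sources and copies) that new placements must avoid.
    occupied: list[tuple[int, int]] = []

    def free(lo: int, hi: int) -> bool:
        return all(hi <= s or lo >= e for s, e in occupied)

    def place() -> int:
        for _attempt in range(500):
            pos = int(rng.integers(0, length - repeat_unit_length + 1))
            if free(pos, pos + repeat_unit_length):
                occupied.append((pos, pos + repeat_unit_length))
                return pos
        raise ValueError(
            "could not place requested repeat content; lower repeat_fraction "
            "or repeat_unit_length"
        )

    placed = 0
    while placed < n_copies_total:
        family_size = min(repeat_copies, n_copies_total - placed)
        if family_size < 2:
            family_size = 2
        src = place()
        for _ in range(family_size - 1):
            dst = place()
            seq[dst : dst + repeat_unit_length] = seq[src : src + repeat_unit_length]
            annotations.append(RepeatAnnotation(dst, dst + repeat_unit_length, src))
        placed += family_size
    return SyntheticGenome("".join(seq), annotations)


def _inject_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitution/insertion/deletion errors, 1:1:1, at error_rate per base."""
    if error_rate == 0:
        return seq
    n = len(seq)
    hit = np.nonzero(rng.random(n) < error_rate)[0]
    if hit.size == 0:
        return seq
    kinds = rng.integers(3, size=hit.size)
    inserts = rng.choice(_BASES, size=hit.size)
    subs = rng.integers(3, size=hit.size)  # offset into the 3 non-matching bases
    out = []
    prev = 0
    for pos, kind, ins, sub in zip(hit, kinds, inserts, subs):
        out.append(seq[prev:pos])
        base = seq[pos]
        if kind == 0:  # substitution
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[sub])
        elif kind == 1:  # insertion before the base
            out.append(str(ins))
            out.append(base)
        # kind == 2: deletion — emit nothing
        prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_reads(
    genome: SyntheticGenome,
    coverage: float = 32.0,
    mean_length: int = 15_000,
    length_sd: int = 3_000,
    error_rate: float = 0.001,
    seed: int = 0,
    rc_fraction: float = 0.0,
) -> list[SimulatedRead]:
    """Sample HiFi-like reads until total bases reach ``coverage`` x genome.

    Lengths are truncated-normal (clipped to [200, genome length]); starts are
    uniform over valid positions for the drawn length; errors are injected
    i.i.d. at ``error_rate`` with substitutions, insertions and deletions in
    equal proportion.  ``rc_fraction`` of reads are emitted reverse-complement
    with strand '-'.  The recorded (start, end) interval is always the true
    forward-strand source interval.
    """
    glen = len(genome)
    if mean_length >= glen:
        raise ValueError("mean_length must be smaller than the genome length")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    target = coverage * glen
    reads: list[SimulatedRead] = []
    total = 0
    while total < target:
        length = int(np.clip(rng.normal(mean_length, length_sd), 200, glen))
        start = int(rng.integers(0, glen - length + 1))
        end = start + length
        raw = genome.sequence[start:end]
        strand = "-" if rng.random() < rc_fraction else "+"
        seq = _inject_errors(raw, error_rate, rng)
        if strand == "-":
            seq = revcomp(seq)
        reads.append(SimulatedRead(f"r{len(reads)}", seq, start, end, strand))
        total += length
    return reads


def reads_to_fasta(reads: list[SimulatedRead], path) -> None:
    """Write reads with coordinates in headers: ``>id start end strand``."""
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.read_id} {read.start} {read.end} {read.strand}\n")
            handle.write(read.sequence + "\n")


def reads_from_fasta(path) -> list[SimulatedRead]:
    """Inverse of :func:`reads_to_fasta`."""
    from Bio import SeqIO

    reads = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.description.split()
        if len(parts) < 4:
            raise ValueError(
                f"read {record.id}: header lacks 'id start end strand' coordinates"
            )
        reads.append(
            SimulatedRead(record.id, str(record.seq).upper(), int(parts[1]), int(parts[2]), parts[3])
        )
    return reads


def _true_overlap(a: SimulatedRead, b: SimulatedRead) -> int:
    """Overlap length of a->b under the positional dovetail conditions, else 0."""
    if a.strand != b.strand:
        return 0
    if a.start < b.start and a.end > b.start and b.end > a.end:
        return a.end - b.start
    return 0


def build_overlap_graph(
    reads: list[SimulatedRead],
    min_overlap: int = 500,
    repeat_annotations: list[RepeatAnnotation] | None = None,
) -> AssemblyGraph:
    """Directed overlap graph from true read coordinates.

    A dovetail edge u->v is created for every same-strand pair with
    start(u) < start(v), end(u) > start(v) and end(v) > end(u), with
    overlap = end(u) - start(v) when that is >= ``min_overlap``.  Containments
    produce no edge.

    When ``repeat_annotations`` is given, additional sequence-implied edges
    are created between reads lying in different copies of a repeat: the
    source read's coordinates are translated into the partner copy's frame
    and the same dovetail test applied.  These edges have identical overlap
    sequences (the copies are exact) but are positionally false, emulating
    the repeat-induced ambiguity a sequence-overlap assembler introduces.
    """
    graph = AssemblyGraph()
    for read in reads:
        graph.add_node(read.read_id, read.strand, len(read.sequence))

    order = sorted(range(len(reads)), key=lambda i: (reads[i].start, reads[i].read_id))
    starts = [reads[i].start for i in order]
    max_len = max((r.end - r.start) for r in reads) if reads else 0

    seen: set[tuple[int, int]] = set()
    import bisect

    for pos_u, u_idx in enumerate(order):
        u = reads[u_idx]
        # candidate partners start within u's interval
        hi = bisect.bisect_left(starts, u.end, lo=pos_u + 1)
        for pos_v in range(pos_u + 1, hi):
            v_idx = order[pos_v]
            v = reads[v_idx]
            ol = _true_overlap(u, v)
            if ol >= min_overlap:
                graph.add_edge(u_idx, v_idx, ol)
                seen.add((u_idx, v_idx))

    if repeat_annotations:
        _add_repeat_edges(graph, reads, order, starts, min_overlap, repeat_annotations, seen)
    return graph


def _add_repeat_edges(graph, reads, order, starts, min_overlap, annotations, seen):
    import bisect

    # Group copies into families (all copies of one source are identical),
    # then every ordered pair of distinct copies gives an equivalence frame
    # (interval of one copy, offset into the other copy's coordinates).
    families: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ann in annotations:
        key = (ann.copy_of, ann.length)
        fam = families.setdefault(key, [(ann.copy_of, ann.copy_of + ann.length)])
        fam.append((ann.start, ann.end))
    frames = []
    for fam in families.values():
        for a_start, a_end in fam:
            for b_start, _ in fam:
                if b_start != a_start:
                    frames.append((a_start, a_end, b_start - a_start))
    for rs, re_, delta in frames:
        for u_idx, u in enumerate(reads):
            # suffix of u inside the repeat copy [rs, re_)
            if not (rs < u.end <= re_):
                continue
            suffix = u.end - max(u.start, rs)
            if suffix < min_overlap:
                continue
            mapped_end = u.end + delta
            # candidate v: starts in [mapped_end - suffix, mapped_end)
            lo = bisect.bisect_left(starts, mapped_end - suffix)
            hi = bisect.bisect_left(starts, mapped_end)
            for pos_v in range(lo, hi):
                v_idx = order[pos_v]
                v = reads[v_idx]
                if v_idx == u_idx or v.strand != u.strand:
                    continue
                ol = mapped_end - v.start
                if ol < min_overlap or v.end <= mapped_end:
                    continue
                # v's matching prefix must lie inside the partner copy
                if v.start < rs + delta or v.start + ol > re_ + delta:
                    continue
                if ol >= min(len(u.sequence), len(v.sequence)):
                    continue
                if (u_idx, v_idx) in seen:
                    continue
                graph.add_edge(u_idx, v_idx, ol)
                seen.add((u_idx, v_idx))
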