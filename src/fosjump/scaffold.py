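"""Greedy contig scaffolding from Fosmid jump links, plus assembly statistics.

Jumps whose two ends map to different contigs imply a joining of one end of
each contig.  A convergent pair end pointing right (+ strand) joins its
contig's tail, an end pointing left joins the head; the estimated gap is the
library insert mean minus the two end-to-contig-edge distances (negative
estimates mean overlapping contigs and are emitted as a 1-N spacer).  Links
aggregated per (contig pair, end pair) below the minimum support are
dropped; the remainder are accepted greedily (support first) whenever they
join two free scaffold ends without a cycle.  This is a deliberately simple
end-joining scaffolder: the acceptance surface is truth recovery on
simulations, not parity with any particular production tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import JumpRecord

HEAD, TAIL = "H", "T"


@dataclass
class ContigLink:
    contig_a: str
    end_a: str  # H | T
    contig_b: str
    end_b: str
    support: int
    gap: float  # mean estimated gap, may be negative


@dataclass
class Scaffold:
    name: str
    parts: list[tuple[str, str, int]]  # (contig, orientation +/-, gap after part)

    def sequence(self, contigs: dict[str, str]) -> str:
        from ._seq import revcomp

        chunks = []
        for i, (c, o, gap) in enumerate(self.parts):
            seq = contigs[c] if o == "+" else revcomp(contigs[c])
            chunks.append(seq)
            if i < len(self.parts) - 1:
                chunks.append("N" * max(gap, 1))
        return "".join(chunks)


def _joined_end(contig_len: int, start: int, end: int, strand: str) -> tuple[str, int]:
    """(contig end joined by this aligned end, distance to that edge)."""
    if strand == "+":
        return TAIL, contig_len - start
    return HEAD, end


def build_link_graph(
    jumps: list[JumpRecord],
    contig_lengths: dict[str, int],
    min_links: int = 2,
    insert_mean: float = 38_000.0,
) -> list[ContigLink]:
    """Aggregate inter-contig jumps into supported, gap-annotated links."""
    acc: dict[tuple[str, str, str, str], list[float]] = {}
    for j in jumps:
        if j.duplicate or j.left.contig == j.right.contig:
            continue
        a, b = j.left, j.right
        ea, da = _joined_end(contig_lengths[a.contig], a.start, a.end, a.strand)
        eb, db = _joined_end(contig_lengths[b.contig], b.start, b.end, b.strand)
        gap = insert_mean - da - db
        key = (a.contig, ea, b.contig, eb)
        if b.contig < a.contig:
            key = (b.contig, eb, a.contig, ea)
        acc.setdefault(key, []).append(gap)
    links = [
        ContigLink(k[0], k[1], k[2], k[3], support=len(gaps), gap=float(np.mean(gaps)))
        for k, gaps in acc.items()
    ]
    return [l for l in links if l.support >= min_links and l.contig_a != l.contig_b]


def greedy_scaffold(
    links: list[ContigLink],
    contigs: dict[str, str] | dict[str, int],
    log: list[str] | None = None,
) -> list[Scaffold]:
    """Order and orient contigs by greedy end-joining.

    Links are tried by support (desc), then combined contig length (desc),
    then lexicographically; one is accepted when both contig ends are free
    and the contigs are not already in the same scaffold (no cycles, no
    self-links).  Unlinked contigs come through as singleton scaffolds.
    """
    length = {c: (len(s) if isinstance(s, str) else int(s)) for c, s in contigs.items()}
    order = sorted(
        links,
        key=lambda l: (
            -l.support,
            -(length[l.contig_a] + length[l.contig_b]),
            l.contig_a,
            l.end_a,
            l.contig_b,
            l.end_b,
        ),
    )
    used: set[tuple[str, str]] = set()
    join: dict[tuple[str, str], tuple[str, str, int]] = {}
    parent = {c: c for c in contigs}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for l in order:
        ka, kb = (l.contig_a, l.end_a), (l.contig_b, l.end_b)
        if l.contig_a == l.contig_b or ka in used or kb in used or find(l.contig_a) == find(l.contig_b):
            if log is not None:
                log.append(f"rejected\t{l.contig_a}.{l.end_a}-{l.contig_b}.{l.end_b}\tsupport={l.support}")
            continue
        used.update((ka, kb))
        gap = max(int(round(l.gap)), 1)
        join[ka] = (l.contig_b, l.end_b, gap)
        join[kb] = (l.contig_a, l.end_a, gap)
        parent[find(l.contig_a)] = find(l.contig_b)

    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for c in contigs:
        if c in seen:
            continue
        # walk leftward from this contig's head to the chain's free outer end
        cur, ent = c, HEAD
        while (cur, ent) in join:
            nb, nb_end, _ = join[(cur, ent)]
            cur, ent = nb, (HEAD if nb_end == TAIL else TAIL)
        # (cur, ent) is now a free end; walk the chain inward from it
        parts: list[tuple[str, str, int]] = []
        node, enter = cur, ent
        while True:
            seen.add(node)
            orient = "+" if enter == HEAD else "-"
            exit_end = TAIL if enter == HEAD else HEAD
            nxt = join.get((node, exit_end))
            parts.append((node, orient, nxt[2] if nxt else 0))
            if nxt is None:
                break
            node, enter = nxt[0], nxt[1]
        scaffolds.append(Scaffold(name=f"scaffold{len(scaffolds) + 1}", parts=parts))
    return scaffolds


def verify_orientation_consistency(scaffolds: list[Scaffold], links: list[ContigLink]) -> bool:
    """Independent post-hoc check: every adjacent pair inside a scaffold must
    be supported by a link joining exactly the facing contig ends."""
    keys = set()
    for l in links:
        keys.add((l.contig_a, l.end_a, l.contig_b, l.end_b))
        keys.add((l.contig_b, l.end_b, l.contig_a, l.end_a))
    for s in scaffolds:
        for (c1, o1, _), (c2, o2, _) in zip(s.parts, s.parts[1:]):
            e1 = TAIL if o1 == "+" else HEAD
            e2 = HEAD if o2 == "+" else TAIL
            if (c1, e1, c2, e2) not in keys:
                return False
    return True


@dataclass
class AssemblyStats:
    num_seqs: int
    sum_len: int
    avg_len: float
    max_len: int
    n50: int
    n_under_30kb: int

    def to_dict(self) -> dict:
        return {
            "num_seqs": self.num_seqs,
            "sum_len": self.sum_len,
            "avg_len": round(self.avg_len, 1),
            "max_len": self.max_len,
            "N50": self.n50,
            "<30kb": self.n_under_30kb,
        }


def assembly_stats(lengths: list[int]) -> AssemblyStats:
    """Standard length statistics of a sequence set (N50 by cumulative half)."""
    if not lengths:
        raise ValueError("empty sequence set")
    from .extract import n50

    return AssemblyStats(
        num_seqs=len(lengths),
        sum_len=int(np.sum(lengths)),
        avg_len=float(np.mean(lengths)),
        max_len=int(np.max(lengths)),
        n50=n50(lengths),
        n_under_30kb=int(np.sum(np.asarray(lengths) < 30_000)),
    )


def write_agp(scaffolds: list[Scaffold], contig_lengths: dict[str, int], path: str) -> None:
    """AGP-style layout: one row per contig part and per gap."""
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\tpart\ttype\tid\torientation\n")
        for s in scaffolds:
            pos = 0
            part = 0
            for i, (c, o, gap) in enumerate(s.parts):
                part += 1
                L = contig_lengths[c]
                fh.write(f"{s.name}\t{pos + 1}\t{pos + L}\t{part}\tW\t{c}\t{o}\n")
                pos += L
                if i < len(s.parts) - 1:
                    g = max(gap, 1)
                    part += 1
                    fh.write(f"{s.name}\t{pos + 1}\t{pos + g}\t{part}\tN\tgap\t+\n")
                    pos += g
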