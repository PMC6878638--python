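"""Circular Fosmid vector maps, in-silico I-SceI digestion and selectability.

The package models two vector geometries:

* a ``pHZAUFOS3``-style map: four I-SceI sites, two of which flank the cloning
  site (releasing the insert together with two short vector stubs, VES1 of
  348 bp and VES2 of 300 bp) and two of which sit in the vector skeleton so
  digestion shatters the backbone into 2-3 kb pieces.  The replication origin
  (oriV) and the chloramphenicol-resistance gene (CmR) lie on opposite sides
  of the cloning site, so a sheared fragment that carries both almost always
  carries both insert/vector junctions — this is what enriches paired-end
  fragments over single-end fragments.
* a ``pcc2FOS``-style map: two sites flanking the cloning site, with oriV and
  CmR on the same side of the cloning site.

The true backbone sequences are not public; the module synthesises a
placeholder sequence that honours the published geometry (total length ~8 kb,
stub lengths, skeleton piece sizes, genuine 18-bp I-SceI motif).  All
downstream logic depends only on this geometry, never on backbone content.

Coordinates are 0-based half-open and wrap modulo the molecule length.  The
I-SceI cut convention is a blunt cut immediately 5' of the motif start (the
enzyme's 4-nt 3' overhang is irrelevant downstream and is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import random_dna, revcomp

ISCEI_MOTIF = "TAGGGATAACAGGGTAAT"  # 18 bp, non-palindromic

FEATURE_NAMES = {"oriV", "CmR", "cloning_site", "VES1", "VES2", "lacZ", "backbone"}

#: Fixed seed for synthesising placeholder backbone sequence; the vector is a
#: published molecule, so its stand-in must be identical across runs.
_VECTOR_SEQ_SEED = 20191126


class VectorError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureInterval:
    """Annotated arc on a circular molecule, 0-based half-open, may wrap."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def span(self, circle_len: int) -> int:
        return (self.end - self.start) % circle_len


def _arc_contains(circle_len: int, a_start: int, a_end_span: int, b_start: int, b_span: int) -> bool:
    """True if arc B (start, span) lies fully inside arc A (start, span)."""
    off = (b_start - a_start) % circle_len
    return off + b_span <= a_end_span


def _arc_overlaps(circle_len: int, a_start: int, a_span: int, b_start: int, b_span: int) -> bool:
    off = (b_start - a_start) % circle_len
    if off < a_span:
        return True
    # b may start before a and run into it
    off2 = (a_start - b_start) % circle_len
    return off2 < b_span


@dataclass
class VectorMap:
    """Circular annotated vector: features, I-SceI sites and sequence."""

    name: str
    length: int
    features: list[FeatureInterval]
    isce1_sites: list[int]
    sequence: str
    #: offset where an insert is ligated in (the cloning site is excised on cloning)
    style: str = "pHZAUFOS3"

    def feature(self, name: str) -> FeatureInterval:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    @property
    def ves1_seq(self) -> str:
        f = self.feature("VES1")
        return self.sequence[f.start : f.end]

    @property
    def ves2_seq(self) -> str:
        f = self.feature("VES2")
        return self.sequence[f.start : f.end]

    def to_config(self) -> str:
        """Feature table as a small structured text config (TSV)."""
        lines = [f"#vector\t{self.name}\t{self.length}\t{self.style}"]
        for f in sorted(self.features, key=lambda x: x.start):
            lines.append(f"feature\t{f.name}\t{f.start}\t{f.end}\t{f.strand}")
        for s in self.isce1_sites:
            lines.append(f"isce1\t{s}")
        return "\n".join(lines) + "\n"

    def to_genbank_like(self) -> str:
        """GenBank-flavoured flat annotation for inspection (not strict GenBank)."""
        out = [f"LOCUS       {self.name}  {self.length} bp  DNA  circular"]
        out.append("FEATURES             Location/Qualifiers")
        for f in sorted(self.features, key=lambda x: x.start):
            loc = f"{f.start + 1}..{f.end}" if f.strand == "+" else f"complement({f.start + 1}..{f.end})"
            out.append(f"     misc_feature    {loc}")
            out.append(f'                     /label="{f.name}"')
        for s in self.isce1_sites:
            out.append(f"     protein_bind    {s + 1}..{s + 18}")
            out.append('                     /label="I-SceI"')
        out.append("//")
        return "\n".join(out) + "\n"


@dataclass
class DigestFragment:
    """Linear fragment produced by cutting a circular molecule at I-SceI sites."""

    source: str
    start: int  # on the circular parent, 0-based
    end: int  # exclusive; may be < start when the fragment wraps
    length: int
    contains: set[str] = field(default_factory=set)
    sequence: str | None = None


@dataclass
class CircularMolecule:
    """A circular molecule (e.g. a Fosmid clone) with annotation carried along."""

    name: str
    sequence: str
    features: list[FeatureInterval]
    isce1_sites: list[int]
    junctions: tuple[int, ...] = ()  # insert/vector junction offsets, if any

    @property
    def length(self) -> int:
        return len(self.sequence)


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = list(motif)


def _default_phzaufos3(overrides: dict[str, tuple[int, int, str]] | None) -> tuple[int, list[FeatureInterval], list[int]]:
    length = 8000
    feats = {
        # VES1: arc between the left flanking cut (618) and the cloning site
        "VES1": (618, 966, "+"),
        "cloning_site": (966, 970, "+"),
        "VES2": (970, 1270, "+"),
        "oriV": (1500, 2200, "+"),
        "CmR": (7000, 7990, "+"),
    }
    sites = [618, 1270, 3719, 6168]
    if overrides:
        feats.update(overrides)
    features = [FeatureInterval(n, s, e, st) for n, (s, e, st) in feats.items()]
    return length, features, sites


def _default_pcc2fos(overrides: dict[str, tuple[int, int, str]] | None) -> tuple[int, list[FeatureInterval], list[int]]:
    length = 8000
    feats = {
        "cloning_site": (966, 970, "+"),
        "lacZ": (970, 1500, "+"),
        "oriV": (2000, 2700, "+"),
        "CmR": (3000, 3990, "+"),
    }
    sites = [618, 1270]
    if overrides:
        feats.update(overrides)
    features = [FeatureInterval(n, s, e, st) for n, (s, e, st) in feats.items()]
    return length, features, sites


def _check_nonoverlapping(length: int, features: list[FeatureInterval]) -> None:
    for i, a in enumerate(features):
        for b in features[i + 1 :]:
            if _arc_overlaps(length, a.start, a.span(length), b.start, b.span(length)):
                raise VectorError(f"features {a.name} and {b.name} overlap")


def build_vector_map(style: str = "pHZAUFOS3", overrides: dict[str, tuple[int, int, str]] | None = None) -> VectorMap:
    """Build a vector map for one of the two supported geometries.

    ``overrides`` maps feature name -> (start, end, strand) and must keep the
    features non-overlapping on the circle.
    """
    if style == "pHZAUFOS3":
        length, features, sites = _default_phzaufos3(overrides)
    elif style == "pcc2FOS":
        length, features, sites = _default_pcc2fos(overrides)
    else:
        raise VectorError(f"unknown vector style: {style!r}")
    names = [f.name for f in features]
    if len(set(names)) != len(names):
        raise VectorError("feature names must be unique")
    for f in features:
        if not (0 <= f.start < length):
            raise VectorError(f"feature {f.name} start out of range")
        if f.name not in FEATURE_NAMES:
            raise VectorError(f"unknown feature name {f.name!r}")
    _check_nonoverlapping(length, features)

    rng = np.random.default_rng(_VECTOR_SEQ_SEED)
    while True:
        seq = list(random_dna(length, rng, gc=0.5))
        # plant the 18-bp motif at each site; skeleton sites on the minus
        # strand to exercise strand handling (the motif is non-palindromic,
        # cutting is strand-independent in the blunt model)
        for i, s in enumerate(sites):
            motif = ISCEI_MOTIF if i % 2 == 0 else revcomp(ISCEI_MOTIF)
            _plant(seq, s, motif)
        text = "".join(seq)
        if _motif_positions(text) == sorted(sites):
            break
    return VectorMap(name=style, length=length, features=features, isce1_sites=sorted(sites), sequence=text, style=style)


def _motif_positions(circular_seq: str) -> list[int]:
    """All I-SceI motif start positions (either strand) on a circular sequence."""
    n = len(circular_seq)
    doubled = circular_seq + circular_seq[: len(ISCEI_MOTIF) - 1]
    hits = set()
    for motif in (ISCEI_MOTIF, revcomp(ISCEI_MOTIF)):
        start = 0
        while True:
            i = doubled.find(motif, start)
            if i < 0 or i >= n:
                break
            hits.add(i)
            start = i + 1
    return sorted(hits)


def make_clone(vector: VectorMap, insert_seq: str, name: str = "clone") -> CircularMolecule:
    """Ligate an insert into the vector's cloning site, returning the clone circle.

    The cloning site interval is excised (blunt cloning into the opened site)
    and replaced by the insert, so the VES1 arc is immediately adjacent to the
    insert start and the VES2 arc to the insert end.  Junction offsets on the
    clone circle are recorded: J1 = insert start, J2 = insert end.
    """
    cs = vector.feature("cloning_site")
    li = len(insert_seq)
    shift = li - (cs.end - cs.start)
    seq = vector.sequence[: cs.start] + insert_seq + vector.sequence[cs.end :]

    def _shift(p: int) -> int:
        return p if p < cs.start else p + shift

    feats = [
        replace(f, start=_shift(f.start), end=_shift(f.end))
        for f in vector.features
        if f.name != "cloning_site"
    ]
    sites = sorted(_shift(s) for s in vector.isce1_sites)
    return CircularMolecule(
        name=name,
        sequence=seq,
        features=feats,
        isce1_sites=sites,
        junctions=(cs.start, cs.start + li),
    )


def isce1_digest(molecule: CircularMolecule, with_sequence: bool = True) -> list[DigestFragment]:
    """Cut a circular molecule at every I-SceI site (blunt, 5' of the motif).

    n sites yield n fragments that partition the circle; each fragment carries
    the labels of the features it overlaps (even partially).
    """
    sites = sorted(set(molecule.isce1_sites))
    n = molecule.length
    if not sites:
        raise VectorError("undigestable: no I-SceI site on molecule")
    frags: list[DigestFragment] = []
    for i, s in enumerate(sites):
        e = sites[(i + 1) % len(sites)]
        span = (e - s) % n or n  # single site -> full-length linear fragment
        contains = {
            f.name
            for f in molecule.features
            if _arc_overlaps(n, s, span, f.start, f.span(n))
        }
        seq = None
        if with_sequence:
            seq = (molecule.sequence * 2)[s : s + span]
        frags.append(DigestFragment(source=molecule.name, start=s, end=(s + span) % n, length=span, contains=contains, sequence=seq))
    return frags


def fragment_contains_fully(molecule: CircularMolecule, frag_start: int, frag_span: int, feature: FeatureInterval) -> bool:
    """True if the feature arc lies fully inside the fragment arc."""
    return _arc_contains(molecule.length, frag_start, frag_span, feature.start, feature.span(molecule.length))


def is_selectable(contains_fully: set[str]) -> bool:
    """A fragment yields a viable, drug-selectable circle iff it carries both
    the replicon (oriV) and the chloramphenicol-resistance gene (CmR) in full."""
    return "oriV" in contains_fully and "CmR" in contains_fully
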