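"""Reference-guided ordering of viral genome fragments on a circle.

Two evidence classes order the fragments of a fragmented circular viral
genome against a fully annotated reference virus:

* **split genes** — a gene whose 5' part is truncated at one fragment's edge
  and whose 3' part is truncated at another fragment's edge evidences that
  the two fragments are physically adjacent (a hard constraint);
* **synteny** — assuming conserved gene order, the forward circular gap
  between the reference gene-order index of one fragment's last mapped ORF
  and the next fragment's first mapped ORF scores each candidate junction
  (score = reference gene count - gap; smaller gaps are better).

Fragment orientation is resolved first (a fragment is flipped when the
majority of its mapped ORFs run on the '-' strand relative to the
reference), then split-gene links are fixed and remaining junctions chosen
greedily by descending synteny score under the single-Hamiltonian-cycle
constraint. Layouts are canonical up to rotation and reflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ScaffoldError(RuntimeError):
    """Raised when split-gene constraints conflict."""


@dataclass
class MappedOrf:
    """An ORF on a fragment with its reference gene assignment.

    ``ref_index`` is the 0-based gene-order index of the best-hit reference
    gene (None when the ORF has no reference hit). ``strand`` is the ORF's
    strand on the fragment; ``ref_strand`` is the matched gene's strand on
    the reference, so the ORF runs with the reference iff the two agree.
    Partial flags are biological (5'-start / 3'-stop truncated by the
    fragment edge).
    """

    name: str
    ref_index: int | None
    strand: str = "+"
    partial5: bool = False
    partial3: bool = False
    ref_strand: str = "+"

    @property
    def relative_strand(self) -> str:
        return "+" if self.strand == self.ref_strand else "-"


@dataclass
class FragmentGeneMap:
    """Ordered ORF content of one fragment (sorted by coordinate)."""

    fragment_id: str
    orfs: list[MappedOrf]
    length: int = 0

    def mapped(self) -> list[MappedOrf]:
        return [o for o in self.orfs if o.ref_index is not None]

    def flipped(self) -> "FragmentGeneMap":
        """The same fragment reverse-complemented: ORF order reverses and
        strands flip; the biological partial flags are unchanged."""
        out = [
            replace(o, strand="-" if o.strand == "+" else "+")
            for o in reversed(self.orfs)
        ]
        return FragmentGeneMap(self.fragment_id, out, self.length)


@dataclass
class SplitGeneLink:
    """Evidence that ``frag5`` (holding a gene's 5' part at its right edge)
    is immediately followed by ``frag3`` (holding the 3' part at its left
    edge)."""

    gene: int | str
    frag5: str
    frag3: str


@dataclass
class Junction:
    src: str
    dst: str
    evidence: str  # "split-gene" | "synteny" | "unsupported"
    score: float = 0.0


@dataclass
class ScaffoldLayout:
    """A circular ordered, oriented arrangement of fragments.

    ``order[i]`` is (fragment_id, orientation); ``junctions[i]`` joins
    ``order[i]`` to ``order[(i+1) % n]``. Canonical up to rotation and
    reflection (see :func:`canonicalize`).
    """

    order: list[tuple[str, str]]
    junctions: list[Junction] = field(default_factory=list)

    def fragment_ids(self) -> list[str]:
        return [f for f, _ in self.order]


def normalize_orientations(maps: list[FragmentGeneMap]
                           ) -> tuple[list[FragmentGeneMap], dict[str, str]]:
    """Flip each fragment whose mapped ORFs are majority '-' relative to the
    reference; returns oriented maps and the per-fragment orientation."""
    out, orient = [], {}
    for gm in maps:
        mapped = gm.mapped()
        minus = sum(1 for o in mapped if o.relative_strand == "-")
        if mapped and minus * 2 > len(mapped):
            out.append(gm.flipped())
            orient[gm.fragment_id] = "-"
        else:
            out.append(gm)
            orient[gm.fragment_id] = "+"
    return out, orient


def _truncated_right(orf: MappedOrf) -> bool:
    return orf.partial3 if orf.strand == "+" else orf.partial5


def _truncated_left(orf: MappedOrf) -> bool:
    return orf.partial5 if orf.strand == "+" else orf.partial3


def detect_split_genes(maps: list[FragmentGeneMap]
                       ) -> tuple[list[SplitGeneLink], list[int]]:
    """Find genes split across the facing edges of two fragments.

    A link is emitted iff the last ORF of one fragment and the first ORF of
    another hit the same reference gene with complementary edge truncation.
    Genes terminal on three or more fragments are ambiguous: no link is
    emitted and the gene is returned in the unresolved list.
    """
    right_end: dict[int, list[str]] = {}
    left_end: dict[int, list[str]] = {}
    for gm in maps:
        if not gm.orfs:
            continue
        last, first = gm.orfs[-1], gm.orfs[0]
        if last.ref_index is not None and _truncated_right(last):
            right_end.setdefault(last.ref_index, []).append(gm.fragment_id)
        if first.ref_index is not None and _truncated_left(first):
            left_end.setdefault(first.ref_index, []).append(gm.fragment_id)
    links, unresolved = [], []
    for gene in sorted(set(right_end) & set(left_end)):
        srcs, dsts = right_end[gene], left_end[gene]
        pairs = [(a, b) for a in srcs for b in dsts if a != b]
        if len(pairs) == 1:
            links.append(SplitGeneLink(gene, pairs[0][0], pairs[0][1]))
        elif len(pairs) > 1:
            unresolved.append(gene)
    return links, unresolved


def synteny_adjacency_scores(maps: list[FragmentGeneMap], ref_gene_count: int
                             ) -> tuple[dict[tuple[str, str], float], list[str]]:
    """Directed junction scores from conserved gene order.

    For each ordered fragment pair (A, B), the terminal mapped ORFs (up to
    the last two of A and the first two of B) vote; the score is
    ``ref_gene_count - gap`` for the smallest forward circular gap between
    their reference indices. Fragments without mapped ORFs are excluded and
    returned separately.
    """
    if ref_gene_count < 1:
        raise ValueError("ref_gene_count must be >= 1")
    usable, skipped = [], []
    for gm in maps:
        if gm.mapped():
            usable.append(gm)
        else:
            skipped.append(gm.fragment_id)
    scores: dict[tuple[str, str], float] = {}
    for a in usable:
        tail = [o.ref_index for o in a.mapped()[-2:]]
        for b in usable:
            if a.fragment_id == b.fragment_id:
                continue
            head = [o.ref_index for o in b.mapped()[:2]]
            gap = min((h - t) % ref_gene_count for t in tail for h in head)
            scores[(a.fragment_id, b.fragment_id)] = float(ref_gene_count - gap)
    return scores, skipped


def order_fragments(links: list[SplitGeneLink],
                    scores: dict[tuple[str, str], float],
                    fragment_ids: list[str] | None = None,
                    orientations: dict[str, str] | None = None
                    ) -> ScaffoldLayout:
    """Assemble the circular fragment order.

    Split-gene links are hard constraints (conflicts raise
    :class:`ScaffoldError`); remaining junctions are chosen greedily by
    descending synteny score, ties broken lexicographically, subject to
    in/out degree 1 and a single cycle. Junctions with neither evidence are
    labelled "unsupported". The result is canonicalized.
    """
    frags = set(fragment_ids or [])
    for link in links:
        frags |= {link.frag5, link.frag3}
    for a, b in scores:
        frags |= {a, b}
    frags = sorted(frags)
    orientations = orientations or {}
    if not frags:
        return ScaffoldLayout([])
    if len(frags) == 1:
        return ScaffoldLayout([(frags[0], orientations.get(frags[0], "+"))])

    succ: dict[str, str] = {}
    pred: dict[str, str] = {}
    evidence: dict[tuple[str, str], Junction] = {}
    for link in links:
        if link.frag5 in succ and succ[link.frag5] != link.frag3:
            raise ScaffoldError(
                f"conflicting split-gene links out of {link.frag5}: "
                f"{succ[link.frag5]} vs {link.frag3}"
            )
        if link.frag3 in pred and pred[link.frag3] != link.frag5:
            raise ScaffoldError(
                f"conflicting split-gene links into {link.frag3}: "
                f"{pred[link.frag3]} vs {link.frag5}"
            )
        succ[link.frag5] = link.frag3
        pred[link.frag3] = link.frag5
        evidence[(link.frag5, link.frag3)] = Junction(
            link.frag5, link.frag3, "split-gene",
            scores.get((link.frag5, link.frag3), 0.0),
        )

    def closes_early(a: str, b: str) -> bool:
        # would a->b close a cycle that excludes some fragment?
        seen = {a}
        cur = b
        while cur in succ:
            if cur == a:
                break
            seen.add(cur)
            cur = succ[cur]
        seen.add(cur)
        return cur == a and len(seen) < len(frags)

    candidates = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    for (a, b), score in candidates:
        if a == b or a in succ or b in pred or closes_early(a, b):
            continue
        succ[a] = b
        pred[b] = a
        evidence[(a, b)] = Junction(a, b, "synteny", score)
    # close any remaining junctions deterministically (no evidence)
    while len(succ) < len(frags):
        a = min(f for f in frags if f not in succ)
        options = [f for f in frags if f not in pred and not closes_early(a, f) and f != a]
        if not options:  # the final closing edge
            options = [f for f in frags if f not in pred and f != a]
        b = options[0]
        succ[a] = b
        pred[b] = a
        evidence.setdefault((a, b), Junction(a, b, "unsupported", 0.0))

    start = frags[0]
    order = [start]
    cur = succ[start]
    while cur != start:
        order.append(cur)
        cur = succ[cur]
    if len(order) != len(frags):
        raise ScaffoldError("fragments do not form a single cycle")
    for link in links:
        if succ.get(link.frag5) != link.frag3:
            raise ScaffoldError(
                f"split-gene link {link.frag5}->{link.frag3} not realized"
            )
    layout = ScaffoldLayout(
        [(f, orientations.get(f, "+")) for f in order],
        [evidence[(order[i], order[(i + 1) % len(order)])]
         for i in range(len(order))],
    )
    return canonicalize(layout)


def _rotate_to_min(layout: ScaffoldLayout) -> ScaffoldLayout:
    n = len(layout.order)
    if n == 0:
        return layout
    ids = [f for f, _ in layout.order]
    i = ids.index(min(ids))
    return ScaffoldLayout(
        layout.order[i:] + layout.order[:i],
        (layout.junctions[i:] + layout.junctions[:i]) if layout.junctions else [],
    )


def reflect(layout: ScaffoldLayout) -> ScaffoldLayout:
    """The same circle traversed the other way, orientations flipped."""
    order = [(f, "-" if o == "+" else "+") for f, o in reversed(layout.order)]
    junctions = [
        Junction(j.dst, j.src, j.evidence, j.score)
        for j in reversed(layout.junctions)
    ]
    if junctions:
        junctions = junctions[1:] + junctions[:1]
    return ScaffoldLayout(order, junctions)


def canonicalize(layout: ScaffoldLayout) -> ScaffoldLayout:
    """Rotation/reflection-invariant representative: prefer the direction
    with more '+' fragments, then the lexicographically smaller order, and
    rotate the lexicographically smallest fragment id to the front."""
    if len(layout.order) <= 1:
        return layout
    fwd = _rotate_to_min(layout)
    rev = _rotate_to_min(reflect(layout))
    plus_fwd = sum(1 for _, o in fwd.order if o == "+")
    plus_rev = sum(1 for _, o in rev.order if o == "+")
    if plus_fwd != plus_rev:
        return fwd if plus_fwd > plus_rev else rev
    return fwd if fwd.order <= rev.order else rev


def global_flip(layout: ScaffoldLayout) -> ScaffoldLayout:
    """Call the other strand of the reconstructed circle forward: the order
    is unchanged, every fragment orientation is complemented."""
    return ScaffoldLayout(
        [(f, "-" if o == "+" else "+") for f, o in layout.order],
        list(layout.junctions),
    )


def equivalent(a: ScaffoldLayout, b: ScaffoldLayout) -> bool:
    """Layout equality up to rotation, reflection and global strand flip.

    A circular dsDNA layout has no intrinsic forward strand, so a layout,
    its reflection, and its global flip all describe the same molecule.
    """
    ca = canonicalize(a).order
    return ca in (canonicalize(b).order, canonicalize(global_flip(b)).order)


def scaffold_fragments(maps: list[FragmentGeneMap], ref_gene_count: int
                       ) -> ScaffoldLayout:
    """End-to-end scaffolding: orient, detect split genes, score synteny,
    order. The pipeline entry point."""
    oriented, orientations = normalize_orientations(maps)
    links, _unresolved = detect_split_genes(oriented)
    scores, _skipped = synteny_adjacency_scores(oriented, ref_gene_count)
    return order_fragments(
        links, scores,
        fragment_ids=[m.fragment_id for m in maps],
        orientations=orientations,
    )


def build_gene_maps(fragments, annotations) -> list[FragmentGeneMap]:
    """Fragment gene maps from called ORFs and their annotations.

    ``annotations`` carry the reference ``gene_order_index`` assigned by
    :func:`nudimine.search.annotate_orfs`; ORF order follows start
    coordinate. Partiality combines the structural edge flags with the
    alignment evidence: a truncated gene can still present an internal ATG
    and look structurally complete, but its alignment then covers only one
    end of the full-length reference protein — the uncovered end is the
    missing one.
    """
    by_frag: dict[str, list] = {f.id: [] for f in fragments}
    for ann in annotations:
        if ann.orf.contig_id in by_frag:
            by_frag[ann.orf.contig_id].append(ann)
    maps = []
    for frag in fragments:
        anns = sorted(by_frag[frag.id], key=lambda a: (a.orf.start, a.orf.end))
        orfs = []
        for a in anns:
            partial5, partial3 = a.orf.partial5, a.orf.partial3
            hit = a.hit
            if hit is not None and hit.subject_cov > 0:
                s_lo, s_hi = hit.subject_range
                subject_len = round((s_hi - s_lo) / hit.subject_cov)
                margin = max(15, 0.15 * subject_len)
                partial5 = partial5 or s_lo > margin
                partial3 = partial3 or s_hi < subject_len - margin
            orfs.append(
                MappedOrf(
                    name=a.orf.name or f"{frag.id}:{a.orf.start}",
                    ref_index=a.gene_order_index,
                    strand=a.orf.strand,
                    partial5=partial5,
                    partial3=partial3,
                    ref_strand=a.ref_strand,
                )
            )
        maps.append(FragmentGeneMap(frag.id, orfs, len(frag.seq)))
    return maps
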