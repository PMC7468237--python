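"""Motif-based haplogroup classification and sub-branch discovery.

A haplogroup tree is a rooted hierarchy in which every node is defined by a
motif of derived variants (position + allele against the marker reference),
optionally with forbidden variants (whose presence excludes the node — used
for sister clades defined by the *absence* of a marker).  A sequence is
classified to the deepest node on a root path whose cumulative motif it
satisfies.  Each node carries a lineage-origin label (South Asian, European,
West Asian, or unassigned), inherited from its parent when not set.

The packaged trees seed the named mtDNA and MSY lineages relevant to Roma
uniparental studies (M5a1b1a and its sub-clades, H107, the H1a1a4b2 Y
branch and sub-branches, J2a, I1a); they are deliberately small and
editable, not a full PhyloTree/ISOGG import.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, MetadataError
from .sequence_io import HaploidAlignment, SampleTable

#: A variant: (1-based reference position, derived allele).
Variant = tuple[int, str]


def parse_variants(text: str) -> tuple[Variant, ...]:
    """Parse ``"3954T,9833C"`` into ``((3954, 'T'), (9833, 'C'))``."""
    text = text.strip()
    if not text or text == ".":
        return ()
    out = []
    for token in text.split(","):
        token = token.strip()
        pos, allele = token[:-1], token[-1].upper()
        if not pos.isdigit() or allele not in "ACGT":
            raise FormatError(f"bad variant token {token!r}")
        out.append((int(pos), allele))
    return tuple(out)


def format_variants(variants: Iterable[Variant]) -> str:
    return ",".join(f"{p}{a}" for p, a in variants) or "."


@dataclass
class MotifNode:
    name: str
    parent: str | None
    required: tuple[Variant, ...]
    forbidden: tuple[Variant, ...] = ()
    origin: str = ""


class MotifTree:
    """Rooted haplogroup hierarchy keyed by node name."""

    def __init__(self, nodes: Sequence[MotifNode]):
        self.nodes: dict[str, MotifNode] = {}
        for n in nodes:
            if n.name in self.nodes:
                raise MetadataError(f"duplicate haplogroup node {n.name!r}")
            self.nodes[n.name] = n
        roots = [n.name for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise MetadataError(f"motif tree must have exactly one root, got {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {n.name: [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise MetadataError(f"node {n.name!r} has unknown parent {n.parent!r}")
                self.children[n.parent].append(n.name)
        for kids in self.children.values():
            kids.sort()
        # cycle check via depth computation
        for name in self.nodes:
            self.depth(name)

    def depth(self, name: str) -> int:
        d, seen = 0, set()
        while self.nodes[name].parent is not None:
            if name in seen:
                raise MetadataError(f"cycle through node {name!r}")
            seen.add(name)
            name = self.nodes[name].parent
            d += 1
        return d

    def path(self, name: str) -> list[str]:
        out = []
        while name is not None:
            out.append(name)
            name = self.nodes[name].parent
        return out[::-1]

    def cumulative_required(self, name: str) -> tuple[Variant, ...]:
        out: list[Variant] = []
        for n in self.path(name):
            out.extend(self.nodes[n].required)
        return tuple(dict.fromkeys(out))

    def origin_of(self, name: str) -> str:
        for n in reversed(self.path(name)):
            if self.nodes[n].origin:
                return self.nodes[n].origin
        return "unassigned"

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifTree":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        nodes = [
            MotifNode(
                name=row["name"],
                parent=None if row["parent"] in ("", ".") else row["parent"],
                required=parse_variants(row.get("required", "")),
                forbidden=parse_variants(row.get("forbidden", "")),
                origin=row.get("origin", ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "name": n.name,
                "parent": n.parent or ".",
                "required": format_variants(n.required),
                "forbidden": format_variants(n.forbidden),
                "origin": n.origin,
            }
            for n in self.nodes.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_tree(marker: str) -> MotifTree:
    """The small editable tree shipped with the package for ``marker``."""
    fname = "mtdna_motifs.tsv" if marker == "mtDNA" else "msy_motifs.tsv"
    return MotifTree.from_tsv(Path(__file__).parent / "data" / fname)


@dataclass
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    matched: tuple[Variant, ...]
    origin: str


class _SeqView:
    """Allele lookup by reference position for one alignment row."""

    def __init__(self, positions: np.ndarray, row: np.ndarray):
        self.index = {int(p): i for i, p in enumerate(positions)}
        self.row = row

    def allele(self, pos: int) -> str | None:
        i = self.index.get(pos)
        return None if i is None else str(self.row[i])

    def has(self, variant: Variant) -> bool:
        return self.allele(variant[0]) == variant[1]


def classify(seq: _SeqView | tuple[np.ndarray, np.ndarray], tree: MotifTree,
             sample_id: str = "") -> HaplogroupCall:
    """Deepest-match classification of one haploid sequence.

    A node matches when every required variant along its root path is
    present and no forbidden variant is carried.  Ties at equal depth break
    by (a) more matched variants, (b) lexicographic name.  When nothing
    below the root matches, the call is the root with origin "unassigned".
    """
    if not isinstance(seq, _SeqView):
        seq = _SeqView(*seq)

    best = (0, 0, "", tree.root)  # (depth, n_matched, reverse-lex key, name)

    def visit(name: str, depth: int, matched: list[Variant]) -> None:
        nonlocal best
        node = tree.nodes[name]
        if any(seq.has(v) for v in node.forbidden):
            return
        if not all(seq.has(v) for v in node.required):
            return
        here = matched + list(node.required)
        key = (depth, len(here))
        bk = (best[0], best[1])
        if key > bk or (key == bk and name < best[3]):
            best = (depth, len(here), "", name)
        for child in tree.children[name]:
            visit(child, depth + 1, here)

    visit(tree.root, 0, [])
    name = best[3]
    matched = tuple(v for v in tree.cumulative_required(name) if seq.has(v))
    origin = tree.origin_of(name) if name != tree.root or matched else "unassigned"
    if name == tree.root:
        origin = "unassigned"
    return HaplogroupCall(sample_id, name, matched, origin)


def classify_alignment(aln: HaploidAlignment, tree: MotifTree) -> list[HaplogroupCall]:
    return [
        classify(_SeqView(aln.positions, aln.matrix[i]), tree, sample_id=sid)
        for i, sid in enumerate(aln.sample_ids)
    ]


def calls_to_frame(calls: Sequence[HaplogroupCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "haplogroup": [c.haplogroup for c in calls],
            "origin": [c.origin for c in calls],
            "matched": [format_variants(c.matched) for c in calls],
        }
    )


# ---------------------------------------------------------------------------
# sub-branch discovery


@dataclass
class Branch:
    """A candidate new sub-branch: variants exclusively shared by a carrier set."""

    haplogroup: str
    variants: tuple[Variant, ...]
    carriers: tuple[str, ...]
    parent: int | None = None  # index of enclosing branch in the result list


def discover_subbranches(aln: HaploidAlignment, calls: Sequence[HaplogroupCall],
                         min_carriers: int = 2,
                         reference_panel: HaploidAlignment | None = None) -> list[Branch]:
    """Find groups of samples within a haplogroup that exclusively share
    derived variants — candidate new sub-branches.

    A variant (position, allele) qualifies for a haplogroup when its carrier
    set is a subset of that haplogroup's samples of size >= ``min_carriers``
    and no other sample in the dataset (nor in ``reference_panel``, if
    given) carries it.  Variants with identical carrier sets are merged into
    one branch.  Output is sorted by carrier-set size (descending) then
    first position; a branch nested inside a larger one points to it via
    ``parent``.
    """
    call_by_sample = {c.sample_id: c.haplogroup for c in calls}
    hg_samples: dict[str, set[str]] = {}
    for c in calls:
        hg_samples.setdefault(c.haplogroup, set()).add(c.sample_id)

    sample_index = {s: i for i, s in enumerate(aln.sample_ids)}
    panel_alleles: dict[int, set[str]] = {}
    if reference_panel is not None:
        for j, pos in enumerate(reference_panel.positions):
            col = reference_panel.matrix[:, j]
            panel_alleles[int(pos)] = {a for a in col if a in "ACGT"}

    by_carriers: dict[tuple[str, frozenset[str]], list[Variant]] = {}
    for j, pos in enumerate(aln.positions):
        col = aln.matrix[:, j]
        for allele in np.unique(col):
            if allele not in "ACGT":
                continue
            carriers = frozenset(
                aln.sample_ids[i] for i in np.where(col == allele)[0]
            )
            if len(carriers) < min_carriers or len(carriers) == aln.n_samples:
                continue
            hgs = {call_by_sample.get(s) for s in carriers}
            if len(hgs) != 1 or None in hgs:
                continue  # carriers must sit inside a single haplogroup
            if allele in panel_alleles.get(int(pos), set()):
                continue
            hg = next(iter(hgs))
            by_carriers.setdefault((hg, carriers), []).append((int(pos), str(allele)))

    branches = [
        Branch(
            haplogroup=hg,
            variants=tuple(sorted(vars_)),
            carriers=tuple(sorted(carriers, key=lambda s: sample_index[s])),
        )
        for (hg, carriers), vars_ in by_carriers.items()
    ]
    branches.sort(key=lambda b: (-len(b.carriers), b.variants[0][0]))

    for i, child in enumerate(branches):
        cset = set(child.carriers)
        best_parent, best_size = None, None
        for k, cand in enumerate(branches):
            if k == i or cand.haplogroup != child.haplogroup:
                continue
            pset = set(cand.carriers)
            if cset < pset and (best_size is None or len(pset) < best_size):
                best_parent, best_size = k, len(pset)
        branches[i].parent = best_parent
    return branches


# ---------------------------------------------------------------------------
# origin proportions


ORIGIN_ORDER = ("South Asian", "European", "West Asian", "unassigned")


def origin_proportions(calls: Sequence[HaplogroupCall],
                       table: SampleTable | None = None) -> pd.DataFrame:
    """Contingency table of lineage origins per marker, with fractions.

    Returns a tidy frame with columns marker, origin, count, fraction;
    fractions sum to 1 within each marker.  Markers come from ``table``
    (joined on sample_id) or default to a single unlabelled stratum.
    """
    if not calls:
        raise DegenerateInputError("no haplogroup calls")
    df = calls_to_frame(calls)
    if table is not None:
        markers = table.df.set_index("sample_id")["marker"]
        df = df.assign(marker=df["sample_id"].map(markers))
        if df["marker"].isna().any():
            missing = df.loc[df["marker"].isna(), "sample_id"].tolist()
            raise MetadataError(f"calls without metadata: {missing}")
    else:
        df = df.assign(marker="all")
    out = (
        df.groupby(["marker", "origin"], sort=True).size().rename("count").reset_index()
    )
    out["fraction"] = out.groupby("marker")["count"].transform(lambda c: c / c.sum())
    order = {o: i for i, o in enumerate(ORIGIN_ORDER)}
    out = out.sort_values(
        ["marker", "origin"],
        key=lambda s: s.map(lambda v: order.get(v, len(order))) if s.name == "origin" else s,
    ).reset_index(drop=True)
    return out
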