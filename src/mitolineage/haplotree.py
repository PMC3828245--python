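"""Haplogroup hierarchy and motif-based classification.

A haplogroup tree is a rooted hierarchy of named clades, each edge carrying
its defining mutations in the same label nomenclature the variant caller
emits; a trailing ``!`` marks a back mutation that restores the ancestral
state (Phylotree convention).  Classification scores every node by the
cumulative motif along its root path — ``matched - missing`` — and assigns
the maximal-score node, breaking ties by matched count, then depth, then
name.  Hotspot positions and poly-C length variants are masked from both
profile and motifs before scoring, mirroring the masking used for tree
building and dating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .refio import (DEFAULT_MASK, MaskPolicy, ReferenceGenome, VariantProfile,
                    load_reference, parse_variant_label)


class HaplotreeError(ValueError):
    pass


@dataclass
class HaplogroupNode:
    name: str
    parent: str | None
    defining_mutations: list[str]


@dataclass
class HaplogroupTree:
    nodes: dict[str, HaplogroupNode]
    root: str

    def __post_init__(self):
        # validate reachability / cycles
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise HaplotreeError(f"cycle through {cur!r}")
                seen.add(cur)
                node = self.nodes.get(cur)
                if node is None:
                    raise HaplotreeError(f"orphan parent {cur!r}")
                cur = node.parent
            if self.root not in seen:
                raise HaplotreeError(f"{name!r} not reachable from root")

    def path(self, name: str) -> list[str]:
        """Root-to-node list of names."""
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


@dataclass
class Assignment:
    sample_id: str
    haplogroup: str
    score: int
    matched: list[str]
    missing: list[str]
    private: list[str]
    ties: list[str] = field(default_factory=list)


def load_haplotree(path: str | Path) -> HaplogroupTree:
    """Load a tree from the three-column TSV (name, parent, motif) or JSON."""
    path = Path(path)
    nodes: dict[str, HaplogroupNode] = {}
    roots: list[str] = []
    if path.suffix == ".json":
        rows = [(d["name"], d.get("parent"), d.get("motif", ""))
                for d in json.loads(path.read_text())]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
        rows = [(r.name, r.parent, r.motif)
                for r in df.itertuples(index=False)]
    for name, parent, motif in rows:
        if name in nodes:
            raise HaplotreeError(f"duplicate haplogroup name {name!r}")
        parent = None if parent in (None, "-", "") else parent
        tokens = [] if motif in ("-", "") else motif.split()
        for t in tokens:
            _check_token(t)
        nodes[name] = HaplogroupNode(name=name, parent=parent,
                                     defining_mutations=tokens)
        if parent is None:
            roots.append(name)
    if len(roots) != 1:
        raise HaplotreeError(f"expected exactly one root, found {roots}")
    return HaplogroupTree(nodes=nodes, root=roots[0])


def load_toy_haplotree() -> HaplogroupTree:
    """The bundled ~40-node toy hierarchy used in tests and examples."""
    return load_haplotree(str(resources.files("mitolineage.data") / "toy_haplotree.tsv"))


def _check_token(token: str) -> None:
    body = token[:-1] if token.endswith("!") else token
    if not body or not body[0].isdigit():
        raise HaplotreeError(f"unparseable motif token {token!r}")


def cumulative_motif(tree: HaplogroupTree, name: str, ref: ReferenceGenome,
                     mask: MaskPolicy = DEFAULT_MASK) -> frozenset[str]:
    """Expected derived-variant labels on the root path to ``name``.

    Back mutations remove the corresponding slot (the ancestral state is
    restored); a later motif at an already-derived slot replaces it.  Tokens
    the mask excludes are skipped on both sides of the comparison.
    """
    state: dict[tuple[int, int], str] = {}
    for node_name in tree.path(name):
        for token in tree.nodes[node_name].defining_mutations:
            back = token.endswith("!")
            v = parse_variant_label(token[:-1] if back else token, ref)
            if mask.excludes(v):
                continue
            slot = (v.position, v.insert_index)
            if back:
                state.pop(slot, None)
            else:
                state[slot] = v.label
    return frozenset(state.values())


def classify(profile: VariantProfile, tree: HaplogroupTree,
             ref: ReferenceGenome | None = None,
             mask: MaskPolicy = DEFAULT_MASK) -> Assignment:
    """Assign the best-matching haplogroup to a masked variant profile."""
    if not tree.nodes:
        raise HaplotreeError("empty haplogroup tree")
    if ref is None:
        ref = load_reference()
    observed = frozenset(
        v.label for v in profile.variants if not mask.excludes(v))
    best: tuple[int, int, int, str] | None = None
    best_name = ""
    per_node: dict[str, tuple[int, int]] = {}
    for name in tree.nodes:
        expected = cumulative_motif(tree, name, ref, mask)
        matched = len(expected & observed)
        missing = len(expected - observed)
        score = matched - missing
        per_node[name] = (score, matched)
        key = (score, matched, tree.depth(name))
        if best is None or key > best[:3] or (key == best[:3] and name < best_name):
            best = (*key, name)
            best_name = name
    assert best is not None
    top_score = best[0]
    ties = sorted(n for n, (s, _) in per_node.items() if s == top_score)
    if len(ties) == 1:
        ties = []
    expected = cumulative_motif(tree, best_name, ref, mask)
    return Assignment(
        sample_id=profile.sample_id,
        haplogroup=best_name,
        score=best[0],
        matched=sorted(expected & observed),
        missing=sorted(expected - observed),
        private=sorted(observed - expected),
        ties=ties,
    )


# ---------------------------------------------------------------------------
# frequency tabulation


def _reporting_label(name: str, tree: HaplogroupTree | None,
                     level) -> str:
    if level is None:
        return name
    if callable(level):
        return level(name)
    if isinstance(level, Mapping):
        # deepest mapped ancestor wins
        if tree is not None and name in tree.nodes:
            for anc in reversed(tree.path(name)):
                if anc in level:
                    return level[anc]
        return level.get(name, name)
    if isinstance(level, (set, frozenset, list, tuple)):
        allowed = set(level)
        if tree is not None and name in tree.nodes:
            for anc in reversed(tree.path(name)):
                if anc in allowed:
                    return anc
        return name
    if level == "top":
        head = ""
        for ch in name:
            if ch.isalpha():
                head += ch
            else:
                break
        return head or name
    raise HaplotreeError(f"unsupported truncation rule {level!r}")


def frequency_table(assignments: Iterable[Assignment], metadata: pd.DataFrame,
                    level=None, tree: HaplogroupTree | None = None) -> pd.DataFrame:
    """Haplogroup frequency (%) per population, plus a Total column.

    ``level`` truncates fine labels into reporting rows: None (as assigned),
    "top" (leading alphabetic prefix), a set of reporting labels (deepest
    listed ancestor), a mapping, or a callable.
    """
    meta = metadata.set_index("sample_id")
    rows = []
    for a in assignments:
        if a.sample_id not in meta.index:
            raise HaplotreeError(f"sample {a.sample_id!r} missing from metadata")
        rows.append({
            "sample_id": a.sample_id,
            "population": meta.loc[a.sample_id, "population"],
            "haplogroup": _reporting_label(a.haplogroup, tree, level),
        })
    df = pd.DataFrame(rows)
    counts = df.pivot_table(index="haplogroup", columns="population",
                            values="sample_id", aggfunc="count", fill_value=0)
    counts["Total"] = counts.sum(axis=1)
    pct = counts / counts.sum(axis=0) * 100.0
    return pct.sort_index()


def component_frequencies(assignments: Iterable[Assignment],
                          metadata: pd.DataFrame,
                          component_map: Mapping[str, str] | None = None,
                          tree: HaplogroupTree | None = None) -> pd.DataFrame:
    """Continental-component frequency (%) per population.

    The component map assigns top-level haplogroups to components (western
    Eurasian, eastern Eurasian, South Asian, African); each sample takes the
    component of the deepest mapped ancestor of its haplogroup, and unmapped
    haplogroups are binned as "other".
    """
    if component_map is None:
        component_map = load_component_map()
    mapping = dict(component_map)
    labeled = [
        Assignment(sample_id=a.sample_id, score=a.score, matched=a.matched,
                   missing=a.missing, private=a.private, ties=a.ties,
                   haplogroup=_component_of(a.haplogroup, mapping, tree))
        for a in assignments
    ]
    table = frequency_table(labeled, metadata, level=None)
    table.index.name = "component"
    return table


def _component_of(name: str, mapping: Mapping[str, str],
                  tree: HaplogroupTree | None) -> str:
    if tree is not None and name in tree.nodes:
        for anc in reversed(tree.path(name)):
            if anc in mapping:
                return mapping[anc]
    return mapping.get(name, "other")


def load_component_map() -> dict[str, str]:
    """Default haplogroup -> component map (western/eastern Eurasian, South
    Asian, African top-level haplogroup lists)."""
    path = resources.files("mitolineage.data") / "component_map.json"
    groups = json.loads(path.read_text())
    return {hg: comp for comp, hgs in groups.items() for hg in hgs}


def assignments_to_tsv(assignments: Iterable[Assignment], path: str | Path,
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\thaplogroup\tscore\tmatched\tmissing\tprivate\tties\n")
        for a in assignments:
            fh.write("\t".join([
                a.sample_id, a.haplogroup, str(a.score),
                " ".join(a.matched), " ".join(a.missing),
                " ".join(a.private), " ".join(a.ties),
            ]) + "\n")
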