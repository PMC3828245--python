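"""Haplogroup tree loading, motif classification, frequency tables."""

import numpy as np
import pandas as pd
import pytest

from mitolineage import haplotree as ht
from mitolineage.refio import DEFAULT_MASK, VariantProfile

from conftest import make_profile


def _write_tree(tmp_path, rows):
    p = tmp_path / "tree.tsv"
    p.write_text("name\tparent\tmotif\n" +
                 "\n".join("\t".join(r) for r in rows) + "\n")
    return p


# ---------------------------------------------------------------------------
# loading


def test_load_three_node_tree(tmp_path):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "73"),
                               ("A1", "A", "263")])
    tree = ht.load_haplotree(p)
    assert tree.root == "root"
    assert tree.depth("A1") == 2
    assert tree.path("A1") == ["root", "A", "A1"]


def test_orphan_parent_rejected(tmp_path):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("B", "missing", "73")])
    with pytest.raises(ht.HaplotreeError, match="orphan"):
        ht.load_haplotree(p)


def test_duplicate_name_rejected(tmp_path):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "73"),
                               ("A", "root", "263")])
    with pytest.raises(ht.HaplotreeError, match="duplicate"):
        ht.load_haplotree(p)


def test_back_mutation_token_parsed(tmp_path, ref):
    p = _write_tree(tmp_path, [("root", "-", "16189"), ("A", "root", "16189!")])
    tree = ht.load_haplotree(p)
    assert tree.nodes["A"].defining_mutations == ["16189!"]
    # cumulative state at A restores the ancestral state
    assert ht.cumulative_motif(tree, "A", ref) == frozenset()
    assert ht.cumulative_motif(tree, "root", ref) == frozenset({"16189"})


# ---------------------------------------------------------------------------
# classification


def test_empty_profile_assigns_root(tmp_path, ref):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "73")])
    tree = ht.load_haplotree(p)
    a = ht.classify(VariantProfile(sample_id="s"), tree, ref)
    assert a.haplogroup == "root"
    assert a.score == 0


def test_full_match_wins(tmp_path, ref):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "73"),
                               ("A1", "A", "263")])
    tree = ht.load_haplotree(p)
    a = ht.classify(make_profile(ref, "s", ["73", "263"]), tree, ref)
    assert (a.haplogroup, len(a.matched), len(a.missing)) == ("A1", 2, 0)


def test_tie_broken_by_matched_count(tmp_path, ref):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "73"),
                               ("A1", "A", "263")])
    tree = ht.load_haplotree(p)
    a = ht.classify(make_profile(ref, "s", ["263"]), tree, ref)
    # root and A1 both score 0; A1 has matched 1 > 0
    assert a.haplogroup == "A1"
    assert set(a.ties) == {"root", "A1"}


def _oracle_classify(profile, tree, ref, mask=DEFAULT_MASK):
    """Independent exhaustive scorer: replay every root path from scratch."""
    observed = {v.label for v in profile.variants if not mask.excludes(v)}
    best = None
    for name in sorted(tree.nodes):
        state = {}
        for node in tree.path(name):
            for token in tree.nodes[node].defining_mutations:
                back = token.endswith("!")
                from mitolineage.refio import parse_variant_label
                v = parse_variant_label(token.rstrip("!"), ref)
                if mask.excludes(v):
                    continue
                slot = (v.position, v.insert_index)
                if back:
                    state.pop(slot, None)
                else:
                    state[slot] = v.label
        expected = set(state.values())
        matched = len(expected & observed)
        score = matched - len(expected - observed)
        key = (score, matched, tree.depth(name))
        if best is None or key > best[0] or (key == best[0] and name < best[1]):
            best = (key, name)
    return best[1]


def _random_tree(rng, n_nodes, positions):
    rows = [("root", "-", "-")]
    names = ["root"]
    pool = list(positions)
    for i in range(1, n_nodes):
        parent = names[int(rng.integers(len(names)))]
        k = int(rng.integers(1, 3))
        motif = []
        for _ in range(k):
            pos = pool[int(rng.integers(len(pool)))]
            motif.append(f"{pos}!" if rng.random() < 0.15 else str(pos))
        name = f"N{i}"
        rows.append((name, parent, " ".join(motif)))
        names.append(name)
    return rows


def test_classification_matches_exhaustive_oracle(tmp_path, ref):
    """Winner equals an independent per-node path-replay scorer on random
    trees up to 50 nodes."""
    rng = np.random.default_rng(99)
    positions = [73, 146, 150, 152, 263, 750, 1438, 2706, 4769, 8860,
                 11719, 14766, 15326, 10398, 12705]
    for trial in range(25):
        rows = _random_tree(rng, int(rng.integers(5, 51)), positions)
        tree = ht.load_haplotree(_write_tree(tmp_path, rows))
        labels = [str(p) for p in rng.choice(positions,
                                             size=int(rng.integers(0, 8)),
                                             replace=False)]
        prof = make_profile(ref, f"s{trial}", labels)
        assert ht.classify(prof, tree, ref).haplogroup == \
            _oracle_classify(prof, tree, ref)


def test_private_variant_never_changes_assignment(ref, toy_tree):
    prof = make_profile(ref, "s", ["73", "263", "1438", "12705", "11719",
                                   "14766", "2706", "7028"])
    base = ht.classify(prof, toy_tree, ref).haplogroup
    private = make_profile(ref, "s", prof.labels() + ["5999"])
    assert ht.classify(private, toy_tree, ref).haplogroup == base


def test_hotspots_masked_from_motifs_and_profile(tmp_path, ref):
    p = _write_tree(tmp_path, [("root", "-", "-"), ("A", "root", "16519"),
                               ("B", "root", "73")])
    tree = ht.load_haplotree(p)
    a = ht.classify(make_profile(ref, "s", ["16519", "73"]), tree, ref)
    # 16519 is invisible on both sides: B wins on the 73 match
    assert a.haplogroup == "B"


# ---------------------------------------------------------------------------
# frequency tables


def _meta(pairs):
    return pd.DataFrame([{"sample_id": s, "population": p} for s, p in pairs])


def _assign(sid, hg):
    return ht.Assignment(sample_id=sid, haplogroup=hg, score=0, matched=[],
                         missing=[], private=[])


def test_single_sample_single_population():
    tab = ht.frequency_table([_assign("a", "H")], _meta([("a", "P1")]))
    assert tab.loc["H", "P1"] == 100.0


def test_three_to_one_split():
    assigns = [_assign(f"s{i}", "H") for i in range(3)] + [_assign("s3", "U")]
    tab = ht.frequency_table(assigns, _meta([(f"s{i}", "P") for i in range(4)]))
    assert tab.loc["H", "P"] == 75.0
    assert tab.loc["U", "P"] == 25.0


def test_columns_sum_to_100(toy_tree):
    rng = np.random.default_rng(3)
    names = list(toy_tree.nodes)
    assigns = [_assign(f"s{i}", names[int(rng.integers(len(names)))])
               for i in range(40)]
    meta = _meta([(f"s{i}", f"P{i % 3}") for i in range(40)])
    tab = ht.frequency_table(assigns, meta, tree=toy_tree)
    assert np.allclose(tab.sum(axis=0), 100.0, atol=0.1)


def test_truncation_to_reporting_labels(toy_tree):
    assigns = [_assign("a", "H13a2a1"), _assign("b", "H1e1a5")]
    meta = _meta([("a", "P"), ("b", "P")])
    tab = ht.frequency_table(assigns, meta, level={"H13", "H1"}, tree=toy_tree)
    assert set(tab.index) == {"H13", "H1"}


def test_missing_sample_in_metadata_errors():
    with pytest.raises(ht.HaplotreeError, match="missing"):
        ht.frequency_table([_assign("a", "H")], _meta([("b", "P")]))


def test_component_frequencies_partition(toy_tree):
    # 9 western (H under R0), 1 south-asian (U2c under U but mapped deeper)
    assigns = [_assign(f"w{i}", "H13") for i in range(9)] + [_assign("s", "U2c")]
    meta = _meta([(f"w{i}", "P") for i in range(9)] + [("s", "P")])
    tab = ht.component_frequencies(assigns, meta, tree=toy_tree)
    assert tab.loc["western_eurasian", "P"] == 90.0
    assert tab.loc["south_asian", "P"] == 10.0


def test_unmapped_haplogroup_binned_as_other(toy_tree):
    tab = ht.component_frequencies([_assign("a", "Zz9")], _meta([("a", "P")]),
                                   tree=toy_tree)
    assert tab.loc["other", "P"] == 100.0
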