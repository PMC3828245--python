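"""Variant scoring against the reference: parsing, alignment, masking,
functional annotation."""

import numpy as np
import pytest

from mitolineage import refio
from mitolineage.refio import (DEFAULT_MASK, MaskPolicy, MtSequence,
                               RefioError, Variant, VariantProfile,
                               apply_mask, apply_variants_to_reference,
                               call_variants, align_to_reference,
                               parse_variant_label)

from conftest import make_profile, random_canonical_variants


# ---------------------------------------------------------------------------
# sequence reading


def test_read_fasta_identity_and_case(tmp_path, ref):
    p = tmp_path / "seqs.fasta"
    p.write_text(f">rCRS\n{ref.bases}\n>low\n{ref.bases.lower()}\n")
    seqs = refio.read_sequences(p, "fasta")
    assert [s.sample_id for s in seqs] == ["rCRS", "low"]
    assert all(len(s.bases) == 16569 for s in seqs)
    assert seqs[1].bases == ref.bases  # upper-cased


def test_read_fasta_duplicate_ids(tmp_path, ref):
    p = tmp_path / "dup.fasta"
    p.write_text(f">a\nACGT\n>a\nACGT\n")
    with pytest.raises(RefioError, match="duplicate"):
        refio.read_sequences(p, "fasta")


def test_non_iupac_character_reported_with_offset():
    with pytest.raises(RefioError, match="offset 2"):
        MtSequence(sample_id="bad", bases="AC#T")


def test_read_genbank_minimal_record(tmp_path, ref):
    body = ref.bases.lower()[:120]
    lines = []
    for i in range(0, 120, 60):
        chunk = body[i:i + 60]
        groups = " ".join(chunk[j:j + 10] for j in range(0, 60, 10))
        lines.append(f"{i + 1:>9} {groups}")
    gb = (
        "LOCUS       KC911275               120 bp    DNA     circular PRI 01-JAN-2014\n"
        "DEFINITION  synthetic mitogenome fragment for parser testing.\n"
        "ACCESSION   KC911275\nVERSION     KC911275.1\n"
        "FEATURES             Location/Qualifiers\n"
        "     source          1..120\nORIGIN\n" + "\n".join(lines) + "\n//\n")
    p = tmp_path / "mini.gb"
    p.write_text(gb)
    recs = refio.read_sequences(p, "genbank")
    assert recs[0].sample_id == "KC911275"
    assert recs[0].bases == ref.bases[:120]


# ---------------------------------------------------------------------------
# alignment


def test_identity_alignment_has_no_differences(ref):
    aln = align_to_reference(MtSequence(sample_id="id", bases=ref.bases), ref)
    assert aln.score == 16569
    prof = call_variants(aln)
    assert len(prof) == 0
    assert prof.compared_length == 16569


def test_single_substitution_at_73(ref):
    seq = ref.bases[:72] + "G" + ref.bases[73:]
    prof = call_variants(align_to_reference(
        MtSequence(sample_id="s", bases=seq), ref))
    assert prof.labels() == ["73"]
    assert prof.variants[0].kind == "transition"


def test_two_base_deletion_left_aligned_matches_window_oracle(ref):
    # plant a deletion inside a 60-bp window and verify against exhaustive
    # placement: every optimal placement of a 2-bp gap, leftmost chosen
    start = 5000  # window 5001..5060 (1-based)
    window = ref.bases[start:start + 60]
    for offset in (10, 25, 40):
        seq = ref.bases[:start + offset] + ref.bases[start + offset + 2:]
        prof = call_variants(align_to_reference(
            MtSequence(sample_id="d", bases=seq), ref))
        dels = [v for v in prof.variants if v.kind == "deletion"]
        assert len(dels) == 2 and dels[1].position == dels[0].position + 1
        # leftmost placement: the gapped window content must equal the oracle
        removed = window[offset:offset + 2]
        best = None
        for cand in range(0, 59):
            if window[:cand] + window[cand + 2:] == window[:offset] + window[offset + 2:]:
                best = cand
                break
        assert dels[0].position == start + best + 1


def test_length_window_and_identity_floor(ref):
    with pytest.raises(RefioError, match="sanity window"):
        align_to_reference(MtSequence(sample_id="short", bases="ACGT" * 100), ref)
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=16569))
    with pytest.raises(RefioError, match="identity"):
        align_to_reference(MtSequence(sample_id="junk", bases=junk), ref)


# ---------------------------------------------------------------------------
# variant calling / nomenclature


def test_insertion_label_from_forced_alignment(ref):
    # C inserted in a context where it cannot shift: after position 100
    base = ref.base(100)
    ins = [b for b in "ACGT" if b != base][0]
    seq = ref.bases[:100] + ins + ref.bases[100:]
    prof = call_variants(align_to_reference(
        MtSequence(sample_id="i", bases=seq), ref))
    assert prof.labels() == [f"100.1{ins}"]


def test_transversion_label_carries_base(ref):
    assert ref.base(16318) == "A"
    seq = ref.bases[:16317] + "T" + ref.bases[16318:]
    prof = call_variants(align_to_reference(
        MtSequence(sample_id="tv", bases=seq), ref))
    assert prof.labels() == ["16318T"]
    assert prof.variants[0].kind == "transversion"


def test_ambiguity_codes_reduce_compared_length(ref):
    seq = ref.bases[:99] + "R" + ref.bases[100:]
    prof = call_variants(align_to_reference(
        MtSequence(sample_id="amb", bases=seq), ref))
    assert len(prof) == 0
    assert prof.compared_length == 16568
    assert prof.uncompared == frozenset({100})


def test_collapsed_deletion_run_label(ref):
    seq = ref.bases[:8280] + ref.bases[8289:]  # remove 8281..8289
    prof = call_variants(align_to_reference(
        MtSequence(sample_id="9bp", bases=seq), ref))
    labels = prof.labels(collapse_deletions=True)
    assert len(labels) == 1 and labels[0].endswith("del") and "-" in labels[0]
    assert len(prof.labels()) == 9  # per-position form


@pytest.mark.parametrize("label", ["73", "16318T", "249del", "315.1C", "950.2AC"])
def test_variant_label_round_trip(label, ref):
    v = parse_variant_label(label, ref)
    assert v.label == label
    assert parse_variant_label(v.label, ref) == v


from hypothesis import given, settings, strategies as hst

_ref_for_hypothesis = refio.load_reference()


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    position=hst.integers(min_value=1, max_value=16569),
    kind=hst.sampled_from(["transition", "transversion", "deletion", "insertion"]),
    pick=hst.integers(min_value=0, max_value=2),
    insert_index=hst.integers(min_value=1, max_value=9),
)
def test_every_variant_label_round_trips(position, kind, pick, insert_index):
    """parse(label(v)) == v for arbitrary variants of every kind."""
    ref = _ref_for_hypothesis
    base = ref.base(position)
    if kind == "transition":
        v = Variant(position=position, kind="transition",
                    derived_state=refio._TRANSITION[base])
    elif kind == "transversion":
        alts = [b for b in "ACGT" if b != base and b != refio._TRANSITION[base]]
        v = Variant(position=position, kind="transversion",
                    derived_state=alts[pick % 2])
    elif kind == "deletion":
        v = Variant(position=position, kind="deletion")
    else:
        v = Variant(position=position, insert_index=insert_index,
                    kind="insertion", derived_state="ACGT"[pick % 4])
    assert parse_variant_label(v.label, ref) == v


def test_variant_roundtrip_through_alignment(ref):
    """Applying a known canonical variant set then re-calling recovers it."""
    rng = np.random.default_rng(1234)
    for _ in range(10):
        variants = random_canonical_variants(ref, rng, n_min=1, n_max=20)
        seq = apply_variants_to_reference(ref, variants)
        prof = call_variants(align_to_reference(
            MtSequence(sample_id="rt", bases=seq), ref))
        assert sorted(prof.labels()) == sorted(v.label for v in variants)


# ---------------------------------------------------------------------------
# masking


def test_default_mask_drops_hotspots(ref):
    prof = make_profile(ref, "m", ["73", "16519"])
    masked = apply_mask(prof)
    assert masked.labels() == ["73"]
    assert prof.labels() == ["73", "16519"]  # input untouched


def test_default_mask_drops_polyc_insertions(ref):
    prof = make_profile(ref, "m", ["309.1C"])
    assert len(apply_mask(prof)) == 0


def test_mask_keeps_substitutions_in_polyc_region(ref):
    prof = make_profile(ref, "m", ["16189"])
    assert apply_mask(prof).labels() == ["16189"]


def test_mask_idempotent_on_random_profiles(ref):
    rng = np.random.default_rng(7)
    for _ in range(5):
        prof = VariantProfile(sample_id="x", variants=tuple(
            random_canonical_variants(ref, rng, 1, 15)))
        once = apply_mask(prof)
        assert apply_mask(once) == once
    empty = VariantProfile(sample_id="e")
    assert apply_mask(empty) == empty


# ---------------------------------------------------------------------------
# functional annotation


def test_control_region_is_noncoding(ref, annotation):
    v = parse_variant_label("16311", ref)
    assert refio.annotate_variant(v, annotation) == "noncoding"


def test_rrna_position_is_rna(ref, annotation):
    v = parse_variant_label("1000", ref)  # inside the small rRNA interval
    assert refio.annotate_variant(v, annotation) == "rna"


def _codon_oracle(ref, annotation, v):
    """Independent codon translation for plus-strand genes."""
    from Bio.Seq import Seq
    rows = annotation.covering(v.position)
    row = rows[rows.type == "coding"].iloc[0]
    assert row.strand == "+"
    off = v.position - row.start
    c0 = row.start + 3 * (off // 3)
    codon = ref.bases[c0 - 1:c0 + 2]
    mut = list(codon)
    mut[v.position - c0] = v.derived_state
    t = lambda c: str(Seq(c).translate(table=2))
    return "synonymous" if t(codon) == t("".join(mut)) else "nonsynonymous"


def test_coding_classification_matches_codon_oracle(ref, annotation):
    """Synonymous/nonsynonymous agrees with Biopython translation under the
    vertebrate mitochondrial code, on many substitutions in single-coverage
    plus-strand genes (ND1)."""
    rng = np.random.default_rng(11)
    checked_syn = checked_non = 0
    for _ in range(300):
        pos = int(rng.integers(3307, 4260))
        base = ref.base(pos)
        alt = "ACGT"[int(rng.integers(4))]
        if alt == base:
            continue
        kind = ("transition"
                if refio._TRANSITION[base] == alt else "transversion")
        v = Variant(position=pos, kind=kind, derived_state=alt)
        got = refio.annotate_variant(v, annotation)
        want = _codon_oracle(ref, annotation, v)
        assert got == want
        checked_syn += got == "synonymous"
        checked_non += got == "nonsynonymous"
    assert checked_syn > 10 and checked_non > 10


def test_coding_indel_is_nonsynonymous_class(ref, annotation):
    v = Variant(position=3400, kind="deletion")
    assert refio.annotate_variant(v, annotation) == "nonsynonymous"


def test_annotation_classes_partition_profile(ref, annotation):
    rng = np.random.default_rng(5)
    variants = random_canonical_variants(ref, rng, 10, 20)
    classes = [refio.annotate_variant(v, annotation) for v in variants]
    assert len(classes) == len(variants)
    assert set(classes) <= {"synonymous", "nonsynonymous", "rna", "noncoding"}
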