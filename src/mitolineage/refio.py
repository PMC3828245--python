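"""Reference-anchored variant scoring of complete mitogenomes.

Every downstream computation in this package works on :class:`VariantProfile`
objects: a sample's differences from the 16,569-bp mtDNA reference coordinate
frame (rCRS numbering), written in the field's standard nomenclature —
transitions by bare position ("73"), transversions with the derived base
("16318T"), deletions as "249del" (with a collapsed "8281-8289del" form for
runs), and insertions as "315.1C".  IUPAC ambiguity codes (heteroplasmies)
yield no variant and shrink the count of compared positions instead, so they
are missing data for every distance and diversity computation.

The packaged reference sequence is a synthetic stand-in for the rCRS (see
``data/synthetic_rcrs.fasta``): it has the correct length and the coordinate
anchors the nomenclature conventions depend on (poly-C tracts at 303-315 and
16184-16194, the hotspot positions 16182/16183/16519), but it is not the
human sequence; the gene annotation table carries the real rCRS gene
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from ._align import banded_global_align, left_normalize

RCRS_LENGTH = 16569
IUPAC = set("ACGTRYSWKMBDHVN")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# vertebrate mitochondrial code
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

VariantKind = Literal["transition", "transversion", "insertion", "deletion"]


class RefioError(ValueError):
    """Raised for malformed sequence input or inconsistent alignments."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReferenceGenome:
    id: str
    bases: str

    def __post_init__(self):
        if self.id == "rCRS" and len(self.bases) != RCRS_LENGTH:
            raise RefioError(f"rCRS reference must be {RCRS_LENGTH} bp, got {len(self.bases)}")
        bad = set(self.bases) - set("ACGT")
        if bad:
            raise RefioError(f"reference alphabet must be ACGT, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        """Base at a 1-based coordinate."""
        return self.bases[position - 1]


@dataclass
class MtSequence:
    sample_id: str
    bases: str
    population: str = ""
    ethnic_group: str = ""
    province: str = ""

    def __post_init__(self):
        if not self.bases:
            raise RefioError(f"{self.sample_id}: empty sequence")
        self.bases = self.bases.upper()
        for off, ch in enumerate(self.bases):
            if ch not in IUPAC:
                raise RefioError(
                    f"{self.sample_id}: non-IUPAC character {ch!r} at offset {off}")


@dataclass(frozen=True, order=True)
class Variant:
    position: int
    insert_index: int = 0
    kind: VariantKind = "transition"
    derived_state: str = ""

    def __post_init__(self):
        if not 1 <= self.position <= RCRS_LENGTH:
            raise RefioError(f"position {self.position} outside 1..{RCRS_LENGTH}")
        if self.kind == "insertion" and self.insert_index < 1:
            raise RefioError("insertions need insert_index >= 1")
        if self.kind != "insertion" and self.insert_index != 0:
            raise RefioError("insert_index must be 0 for non-insertions")
        if self.kind == "deletion" and self.derived_state != "":
            raise RefioError("deletions carry no derived state")

    @property
    def label(self) -> str:
        if self.kind == "transition":
            return str(self.position)
        if self.kind == "transversion":
            return f"{self.position}{self.derived_state}"
        if self.kind == "deletion":
            return f"{self.position}del"
        return f"{self.position}.{self.insert_index}{self.derived_state}"

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")


def parse_variant_label(label: str, ref: ReferenceGenome) -> Variant:
    """Parse a canonical variant label back into a :class:`Variant`.

    The reference is needed to recover the derived state of a bare-position
    transition label and to reject 'transversion' labels that actually denote
    transitions.
    """
    label = label.strip()
    if not label:
        raise RefioError("empty variant label")
    if label.endswith("del"):
        body = label[:-3]
        if "-" in body:
            lo, hi = body.split("-")
            raise RefioError(
                f"collapsed deletion label {label!r} spans {lo}-{hi}; parse per-position labels")
        return Variant(position=int(body), kind="deletion")
    if "." in label:
        pos_s, rest = label.split(".", 1)
        idx = ""
        for ch in rest:
            if ch.isdigit():
                idx += ch
            else:
                break
        base = rest[len(idx):]
        if not idx or base == "" or any(b not in "ACGT" for b in base):
            raise RefioError(f"malformed insertion label {label!r}")
        return Variant(position=int(pos_s), insert_index=int(idx),
                       kind="insertion", derived_state=base)
    if label[-1].isdigit():
        pos = int(label)
        anc = ref.base(pos)
        return Variant(position=pos, kind="transition",
                       derived_state=_TRANSITION[anc])
    base = label[-1]
    if base not in "ACGT":
        raise RefioError(f"malformed variant label {label!r}")
    pos = int(label[:-1])
    anc = ref.base(pos)
    kind = "transition" if _TRANSITION[anc] == base else "transversion"
    return Variant(position=pos, kind=kind, derived_state=base)


@dataclass(frozen=True)
class VariantProfile:
    sample_id: str
    variants: tuple[Variant, ...] = ()
    uncompared: frozenset[int] = frozenset()

    def __post_init__(self):
        ordered = tuple(sorted(self.variants,
                               key=lambda v: (v.position, v.insert_index)))
        object.__setattr__(self, "variants", ordered)
        seen = set()
        for v in ordered:
            key = (v.position, v.insert_index)
            if key in seen:
                raise RefioError(
                    f"{self.sample_id}: duplicate variant slot {key}")
            seen.add(key)

    @property
    def compared_length(self) -> int:
        return RCRS_LENGTH - len(self.uncompared)

    def labels(self, collapse_deletions: bool = False) -> list[str]:
        if not collapse_deletions:
            return [v.label for v in self.variants]
        out: list[str] = []
        run: list[int] = []
        for v in self.variants:
            if v.kind == "deletion":
                if run and v.position == run[-1] + 1:
                    run.append(v.position)
                else:
                    if run:
                        out.append(_del_label(run))
                    run = [v.position]
            else:
                if run:
                    out.append(_del_label(run))
                    run = []
                out.append(v.label)
        if run:
            out.append(_del_label(run))
        return out

    def substitutions(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if not v.is_indel)

    def label_set(self) -> frozenset[str]:
        return frozenset(v.label for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _del_label(run: list[int]) -> str:
    if len(run) == 1:
        return f"{run[0]}del"
    return f"{run[0]}-{run[-1]}del"


@dataclass(frozen=True)
class MaskPolicy:
    excluded_positions: frozenset[int] = frozenset({16182, 16183, 16519})
    excluded_regions: tuple[tuple[int, int], ...] = ((303, 315), (16184, 16194))
    drop_length_variants_in_regions: bool = True

    def excludes(self, v: Variant) -> bool:
        if v.position in self.excluded_positions:
            return True
        if self.drop_length_variants_in_regions and v.is_indel:
            for lo, hi in self.excluded_regions:
                if lo <= v.position <= hi:
                    return True
        return False


DEFAULT_MASK = MaskPolicy()
NO_MASK = MaskPolicy(excluded_positions=frozenset(), excluded_regions=(),
                     drop_length_variants_in_regions=False)


# ---------------------------------------------------------------------------
# reference / sequence IO


def load_reference() -> ReferenceGenome:
    """Load the packaged 16,569-bp reference (synthetic rCRS stand-in)."""
    path = resources.files("mitolineage.data") / "synthetic_rcrs.fasta"
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(id="rCRS", bases=str(rec.seq).upper())


def read_sequences(path: str | Path, format: str = "fasta") -> list[MtSequence]:
    """Read mitogenome records from a FASTA or GenBank flat file."""
    if format not in ("fasta", "genbank"):
        raise RefioError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise RefioError(f"no such file: {path}")
    out: list[MtSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), format):
        sid = rec.name if format == "genbank" and rec.name else rec.id
        if sid in seen:
            raise RefioError(f"duplicate sequence id {sid!r}")
        seen.add(sid)
        out.append(MtSequence(sample_id=sid, bases=str(rec.seq)))
    if not out:
        raise RefioError(f"{path}: no records parsed as {format}")
    return out


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, population, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise RefioError("metadata needs at least sample_id and population columns")
    return df


def attach_metadata(seqs: Iterable[MtSequence], metadata: pd.DataFrame) -> list[MtSequence]:
    by_id = metadata.set_index("sample_id")
    out = []
    for s in seqs:
        if s.sample_id not in by_id.index:
            raise RefioError(f"sample {s.sample_id!r} missing from metadata")
        row = by_id.loc[s.sample_id]
        out.append(replace(
            s,
            population=str(row.get("population", "")),
            ethnic_group=str(row.get("ethnic_group", "")),
            province=str(row.get("province", "")),
        ))
    return out


# ---------------------------------------------------------------------------
# alignment


@dataclass
class Alignment:
    """Reference-anchored gapped alignment (equal-length gapped strings)."""
    sample_id: str
    ref_gapped: str
    qry_gapped: str
    score: int
    population: str = ""

    @property
    def identity(self) -> float:
        same = sum(1 for a, b in zip(self.ref_gapped, self.qry_gapped) if a == b)
        return same / len(self.ref_gapped)


def align_to_reference(seq: MtSequence, ref: ReferenceGenome,
                       match: int = 1, mismatch: int = 1,
                       gap_open: int = 8, gap_extend: int = 1,
                       length_window: tuple[int, int] = (16069, 17069),
                       identity_floor: float = 0.90) -> Alignment:
    """Globally align a sample to the reference, gaps left-aligned.

    Sequences are assumed to be linear strings already in rCRS register
    (position 1 first); circular rotations are not detected and surface as
    an identity-floor failure instead.
    """
    lo, hi = length_window
    if not lo <= len(seq.bases) <= hi:
        raise RefioError(
            f"{seq.sample_id}: length {len(seq.bases)} outside sanity window {lo}..{hi}")
    score, ops = banded_global_align(ref.bases, seq.bases, match=match,
                                     mismatch=mismatch, gap_open=gap_open,
                                     gap_extend=gap_extend)
    r, q = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            r.append(ref.bases[i]); q.append(seq.bases[j]); i += 1; j += 1
        elif op == "D":
            r.append(ref.bases[i]); q.append("-"); i += 1
        else:
            r.append("-"); q.append(seq.bases[j]); j += 1
    left_normalize(r, q)
    aln = Alignment(sample_id=seq.sample_id, ref_gapped="".join(r),
                    qry_gapped="".join(q), score=score,
                    population=seq.population)
    if aln.identity < identity_floor:
        raise RefioError(
            f"{seq.sample_id}: alignment identity {aln.identity:.3f} below "
            f"{identity_floor}; not a mitogenome in rCRS register?")
    return aln


def call_variants(alignment: Alignment) -> VariantProfile:
    """Score an alignment into a variant profile in standard nomenclature."""
    variants: list[Variant] = []
    uncompared: set[int] = set()
    pos = 0  # last consumed reference coordinate (1-based)
    insert_index = 0
    for a, b in zip(alignment.ref_gapped, alignment.qry_gapped):
        if a != "-":
            pos += 1
            insert_index = 0
            if b == "-":
                variants.append(Variant(position=pos, kind="deletion"))
            elif b not in "ACGT":
                uncompared.add(pos)  # IUPAC ambiguity: missing data
            elif b != a:
                kind = "transition" if _TRANSITION[a] == b else "transversion"
                variants.append(Variant(position=pos, kind=kind, derived_state=b))
        else:
            if pos == 0:
                raise RefioError("insertion before reference position 1")
            insert_index += 1
            if b not in "ACGT":
                continue  # ambiguous inserted base: ignore
            variants.append(Variant(position=pos, insert_index=insert_index,
                                    kind="insertion", derived_state=b))
    if pos != RCRS_LENGTH:
        raise RefioError(
            f"alignment covers {pos} reference positions, expected {RCRS_LENGTH}")
    return VariantProfile(sample_id=alignment.sample_id, variants=tuple(variants),
                          uncompared=frozenset(uncompared))


def apply_mask(profile: VariantProfile, policy: MaskPolicy = DEFAULT_MASK) -> VariantProfile:
    """Drop hotspot and poly-C length variants; idempotent, input untouched."""
    kept = tuple(v for v in profile.variants if not policy.excludes(v))
    return VariantProfile(sample_id=profile.sample_id, variants=kept,
                          uncompared=profile.uncompared)


def apply_variants_to_reference(ref: ReferenceGenome,
                                variants: Sequence[Variant]) -> str:
    """Build the sequence that carries exactly the given variants.

    The inverse of :func:`call_variants` for unambiguous inputs; used by the
    simulator and by round-trip tests.
    """
    per_pos: dict[int, list[Variant]] = {}
    for v in variants:
        per_pos.setdefault(v.position, []).append(v)
    out: list[str] = []
    for pos in range(1, len(ref) + 1):
        here = sorted(per_pos.get(pos, []), key=lambda v: v.insert_index)
        base = ref.base(pos)
        emitted = False
        for v in here:
            if v.kind == "deletion":
                emitted = True
            elif v.kind != "insertion":
                out.append(v.derived_state)
                emitted = True
        if not emitted:
            out.append(base)
        for v in here:
            if v.kind == "insertion":
                out.append(v.derived_state)
    return "".join(out)


# ---------------------------------------------------------------------------
# functional annotation


@dataclass
class Annotation:
    """Gene intervals tiling 1..16569, with strand, for codon classification."""
    table: pd.DataFrame
    ref: ReferenceGenome

    def __post_init__(self):
        covered = set()
        for row in self.table.itertuples():
            covered.update(range(row.start, row.end + 1))
        missing = set(range(1, RCRS_LENGTH + 1)) - covered
        if missing:
            raise RefioError(
                f"annotation does not tile 1..{RCRS_LENGTH}; first gap at {min(missing)}")

    def covering(self, position: int) -> pd.DataFrame:
        t = self.table
        return t[(t.start <= position) & (position <= t.end)]


def load_annotation(ref: ReferenceGenome | None = None) -> Annotation:
    if ref is None:
        ref = load_reference()
    path = resources.files("mitolineage.data") / "mt_annotation.tsv"
    df = pd.read_csv(str(path), sep="\t")
    # intergenic spacers become noncoding rows so the table tiles the genome
    covered = set()
    for row in df.itertuples():
        covered.update(range(row.start, row.end + 1))
    spacers = []
    pos = 1
    while pos <= RCRS_LENGTH:
        if pos in covered:
            pos += 1
            continue
        start = pos
        while pos <= RCRS_LENGTH and pos not in covered:
            pos += 1
        spacers.append({"gene": f"NC_{start}", "start": start, "end": pos - 1,
                        "type": "noncoding", "strand": "+"})
    if spacers:
        df = pd.concat([df, pd.DataFrame(spacers)], ignore_index=True)
    return Annotation(table=df, ref=ref)


def _codon_effect(v: Variant, row, ref: ReferenceGenome) -> str | None:
    """synonymous/nonsynonymous for a substitution in one coding gene.

    Returns None when the position falls in an incomplete trailing codon
    (mitochondrial genes may end on a partial stop completed by
    polyadenylation), which is treated as untranslated.
    """
    start, end, strand = row.start, row.end, row.strand
    if strand == "+":
        off = v.position - start
        c0 = start + 3 * (off // 3)
        if c0 + 2 > end:
            return None
        codon = ref.bases[c0 - 1:c0 + 2]
        mut = list(codon)
        mut[v.position - c0] = v.derived_state
    else:
        off = end - v.position
        c_hi = end - 3 * (off // 3)
        if c_hi - 2 < start:
            return None
        codon_fwd = ref.bases[c_hi - 3:c_hi]
        codon = _revcomp(codon_fwd)
        mut_fwd = list(codon_fwd)
        mut_fwd[v.position - (c_hi - 2)] = v.derived_state
        mut = list(_revcomp("".join(mut_fwd)))
    aa0 = _translate_codon(codon if isinstance(codon, str) else "".join(codon))
    aa1 = _translate_codon("".join(mut))
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _translate_codon(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def annotate_variant(v: Variant, annotation: Annotation) -> str:
    """Classify a variant as synonymous / nonsynonymous / rna / noncoding."""
    rows = annotation.covering(v.position)
    if rows.empty:
        raise RefioError(f"position {v.position} not covered by annotation")
    kinds = set(rows.type)
    if "coding" in kinds:
        if v.is_indel:
            return "nonsynonymous"  # frame-disrupting by convention
        effects = set()
        for row in rows[rows.type == "coding"].itertuples():
            eff = _codon_effect(v, row, annotation.ref)
            if eff is not None:
                effects.add(eff)
        if "nonsynonymous" in effects:
            return "nonsynonymous"
        if "synonymous" in effects:
            return "synonymous"
        return "noncoding"  # incomplete trailing codon only
    if kinds & {"rrna", "trna"}:
        return "rna"
    return "noncoding"


# ---------------------------------------------------------------------------
# profile IO


def write_profiles_tsv(profiles: Iterable[VariantProfile], path: str | Path,
                       collapse_deletions: bool = False,
                       header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for p in profiles:
            fh.write(f"{p.sample_id}\t{' '.join(p.labels(collapse_deletions))}\n")


def read_profiles_tsv(path: str | Path, ref: ReferenceGenome) -> list[VariantProfile]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, _, rest = line.partition("\t")
            labels = [t for t in rest.split(" ") if t]
            variants = tuple(parse_variant_label(t, ref) for t in labels)
            out.append(VariantProfile(sample_id=sid, variants=variants))
    return out


def profile_to_json(profile: VariantProfile) -> str:
    doc = {
        "sample_id": profile.sample_id,
        "compared_length": profile.compared_length,
        "variants": [
            {"position": v.position, "insert_index": v.insert_index,
             "kind": v.kind, "derived_state": v.derived_state, "label": v.label}
            for v in profile.variants
        ],
        "uncompared_positions": sorted(profile.uncompared),
    }
    return json.dumps(doc, indent=2, sort_keys=True)
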