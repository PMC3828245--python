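"""End-to-end orchestration: config -> report bundle.

A single config (YAML or JSON) drives the full analysis.  Hotspot/poly-C
masking is applied where the method calls for it — classification, network
building and dating — while diversity and structure statistics default to
the unmasked profiles, mirroring how the exclusion list is scoped to the
dating calculations.  Every output file carries the config hash and seed in
a header comment, and a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diversity as div
from . import haplotree as ht
from . import network as net
from . import refio
from . import rho_clock as rc
from . import simulate as sim
from . import structure as st

log = logging.getLogger("mitolineage")

ALL_STAGES = ("profile", "classify", "network", "date", "diversity", "structure")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sequences: str = ""
    metadata: str = ""
    haplotree: str = ""              # empty -> bundled toy tree
    output_dir: str = "mitolineage_out"
    input_format: str = "fasta"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_permutations: int = 10000
    complete_deletion: bool = True
    include_indels: bool = False
    mask_diversity: bool = False     # apply the hotspot mask to diversity too
    mask_excluded_positions: tuple[int, ...] = (16182, 16183, 16519)
    mask_excluded_regions: tuple[tuple[int, int], ...] = ((303, 315), (16184, 16194))
    clocks: tuple[dict, ...] = (
        {"name": "complete_genome", "rate": rc.DEFAULT_RATE,
         "effective_sites": refio.RCRS_LENGTH},
    )
    mds_restarts: int = 8
    d_significance_reps: int = 2000

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "mask_excluded_positions" in kwargs:
            kwargs["mask_excluded_positions"] = tuple(kwargs["mask_excluded_positions"])
        if "mask_excluded_regions" in kwargs:
            kwargs["mask_excluded_regions"] = tuple(
                tuple(r) for r in kwargs["mask_excluded_regions"])
        if "clocks" in kwargs:
            kwargs["clocks"] = tuple(kwargs["clocks"])
        return cls(**kwargs)

    def mask_policy(self) -> refio.MaskPolicy:
        return refio.MaskPolicy(
            excluded_positions=frozenset(self.mask_excluded_positions),
            excluded_regions=tuple(self.mask_excluded_regions),
            drop_length_variants_in_regions=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def validate(config: PipelineConfig) -> list[str]:
    """Report config problems without raising."""
    findings: list[str] = []
    for label, path in (("sequences", config.sequences),
                        ("metadata", config.metadata)):
        if not path:
            findings.append(f"missing input: no {label} path configured")
        elif not Path(path).exists():
            findings.append(f"missing input: {label} file {path!r} not found")
    if config.haplotree and not Path(config.haplotree).exists():
        findings.append(f"missing input: haplotree file {config.haplotree!r} not found")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        findings.append(f"unknown stages: {sorted(unknown)}")
    if config.seed is None:
        findings.append("unset seed")
    if config.sequences and Path(config.sequences).exists() \
            and config.metadata and Path(config.metadata).exists():
        try:
            seqs = refio.read_sequences(config.sequences, config.input_format)
            meta = refio.load_metadata(config.metadata)
            known = set(meta["sample_id"])
            for s in seqs:
                if s.sample_id not in known:
                    findings.append(f"unmapped sample: {s.sample_id}")
            pops = meta["population"].value_counts()
            for pop, cnt in pops.items():
                if cnt < 2:
                    findings.append(f"singleton population: {pop}")
        except Exception as exc:  # validation never throws
            findings.append(f"unreadable input: {exc}")
    return findings


def _header(config: PipelineConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def _write_df(df: pd.DataFrame, path: Path, config: PipelineConfig,
              index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(config)}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages in order; return the output bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    ref = refio.load_reference()
    mask = config.mask_policy()
    runlog: list[str] = [f"# {_header(config)}"]

    def logline(stage: str, msg: str) -> None:
        line = f"{stage}\t{msg}"
        runlog.append(line)
        log.info(line)

    profiles = masked = None
    meta = None

    def need_profiles():
        nonlocal profiles, masked, meta
        if profiles is not None:
            return
        seqs = refio.read_sequences(config.sequences, config.input_format)
        meta_df = refio.load_metadata(config.metadata)
        seqs = refio.attach_metadata(seqs, meta_df)
        prof = []
        for s in seqs:
            aln = refio.align_to_reference(s, ref)
            prof.append(refio.call_variants(aln))
        profiles = prof
        masked = [refio.apply_mask(p, mask) for p in prof]
        meta = meta_df

    try:
        if "profile" in config.stages:
            need_profiles()
            path = out / "profiles.tsv"
            refio.write_profiles_tsv(profiles, path,
                                     header_comment=_header(config))
            outputs["profiles"] = path
            logline("profile", f"records_in={len(profiles)} records_out={len(profiles)}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("profile", str(exc)) from exc

    try:
        if "classify" in config.stages:
            need_profiles()
            tree = (ht.load_haplotree(config.haplotree) if config.haplotree
                    else ht.load_toy_haplotree())
            assignments = [ht.classify(p, tree, ref, mask) for p in masked]
            path = out / "assignments.tsv"
            ht.assignments_to_tsv(assignments, path, header_comment=_header(config))
            outputs["assignments"] = path
            freq = ht.frequency_table(assignments, meta, tree=tree)
            _write_df(freq, out / "haplogroup_frequencies.tsv", config)
            outputs["haplogroup_frequencies"] = out / "haplogroup_frequencies.tsv"
            comp = ht.component_frequencies(assignments, meta, tree=tree)
            _write_df(comp, out / "component_frequencies.tsv", config)
            outputs["component_frequencies"] = out / "component_frequencies.tsv"
            logline("classify", f"records_in={len(masked)} records_out={len(assignments)}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    genealogy = None
    try:
        if "network" in config.stages or "date" in config.stages:
            need_profiles()
            classes = net.collapse_haplotypes(masked)
            network = net.build_network(classes)
            net.export_network(network, out / "network_edges.tsv",
                               header_comment=_header(config))
            outputs["network_edges"] = out / "network_edges.tsv"
            root_profile = refio.VariantProfile(sample_id="rCRS_root")
            genealogy = net.extract_genealogy(network, root_profile)
            net.export_genealogy(genealogy, out / "genealogy.nwk",
                                 out / "genealogy_edges.tsv",
                                 header_comment=_header(config))
            outputs["genealogy"] = out / "genealogy.nwk"
            logline("network", f"records_in={len(masked)} classes={len(classes)} "
                               f"nodes={network.number_of_nodes()}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc

    try:
        if "date" in config.stages and genealogy is not None:
            clocks = [rc.ClockModel(name=c.get("name", "complete_genome"),
                                    rate=float(c.get("rate", rc.DEFAULT_RATE)),
                                    effective_sites=int(c.get("effective_sites",
                                                              refio.RCRS_LENGTH)))
                      for c in config.clocks]
            ages = rc.clade_ages(genealogy, clocks, clade="all_samples")
            _write_df(ages, out / "clade_ages.tsv", config, index=False)
            outputs["clade_ages"] = out / "clade_ages.tsv"
            logline("date", f"clocks={len(clocks)}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("date", str(exc)) from exc

    try:
        if "diversity" in config.stages:
            need_profiles()
            src = masked if config.mask_diversity else profiles
            table = div.summarize(src, meta,
                                  include_indels_in_sites=config.include_indels,
                                  complete_deletion=config.complete_deletion,
                                  d_significance_reps=config.d_significance_reps,
                                  seed=config.seed)
            _write_df(table, out / "diversity.tsv", config, index=False)
            outputs["diversity"] = out / "diversity.tsv"
            logline("diversity", f"records_in={len(src)} rows={len(table)}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diversity", str(exc)) from exc

    try:
        if "structure" in config.stages:
            need_profiles()
            src = masked if config.mask_diversity else profiles
            pops = _populations(src, meta)
            dm = st.distance_matrix(src, include_indels=config.include_indels,
                                    complete_deletion=config.complete_deletion)
            res = st.amova(dm, pops, n_perm=config.n_permutations,
                           seed=config.seed)
            _write_df(res.to_frame(), out / "amova.tsv", config, index=False)
            outputs["amova"] = out / "amova.tsv"
            phist, pvals = st.pairwise_phist(dm, pops,
                                             n_perm=config.n_permutations,
                                             seed=config.seed)
            _write_df(phist, out / "phist.tsv", config)
            outputs["phist"] = out / "phist.tsv"
            _write_df(pvals, out / "phist_pvalues.tsv", config)
            emb = st.mds(phist, seed=config.seed, restarts=config.mds_restarts)
            coords = pd.DataFrame(emb.coords, index=emb.labels,
                                  columns=["dim1", "dim2"][:emb.coords.shape[1]])
            coords["stress"] = emb.stress
            _write_df(coords, out / "mds.tsv", config)
            outputs["mds"] = out / "mds.tsv"
            logline("structure", f"populations={len(set(pops))} "
                                 f"phi_st={res.phi_statistics['Phi_ST']:.4f}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("structure", str(exc)) from exc

    (out / "run_log.tsv").write_text("\n".join(runlog) + "\n")
    outputs["run_log"] = out / "run_log.tsv"
    return outputs


def _populations(profiles, meta: pd.DataFrame) -> list[str]:
    lookup = meta.set_index("sample_id")["population"]
    return [str(lookup.loc[p.sample_id]) for p in profiles]
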