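"""Pipeline orchestration: classify -> collapse -> statistics -> network -> tree.

One validated configuration drives every stage and writes a directory of
artifacts (classification TSV, per-group diversity/neutrality JSON+TSV,
network exports, Newick tree, composition summary, JSON run manifest).
Re-running with the same inputs and configuration reproduces every
artifact byte-for-byte apart from the manifest timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .haplonet import export_network, median_joining
from .phylo import nj_tree, tn93_matrix, write_newick
from .popgen import collapse_haplotypes, diversity_stats, neutrality_stats
from .rflp import (
    APOI,
    MED_LIBRARY,
    ClassificationResult,
    EnzymeSpec,
    PatternLibrary,
    RflpPattern,
    classify_pattern,
    digest,
    extract_amplicon,
)
from .seqio import (
    SpecimenRecord,
    join_sequences_metadata,
    read_fasta,
    read_metadata,
)

logger = logging.getLogger(__name__)

METADATA_FIELDS = ("region", "locality", "host_plant", "setting", "year")


@dataclass
class PipelineConfig:
    fasta: str = ""
    metadata: str = ""
    outdir: str = "coipop_out"
    fwd_primer: str | None = None
    rev_primer: str | None = None
    max_mismatch: int = 0
    expected_length: int = 866
    length_tolerance: int = 20
    enzyme: EnzymeSpec = field(default_factory=lambda: APOI)
    patterns: PatternLibrary = field(default_factory=lambda: MED_LIBRARY)
    comparison_policy: str = "complete_deletion"
    match_mode: str = "cut_set_exact"
    gel_min_visible: int = 25
    epsilon: int = 0
    grouping: tuple[str, ...] = ("region", "setting")
    network_label: str | None = None  # default: most frequent classified label
    seed: int = 0
    log_level: str = "INFO"

    _KNOWN = {
        "fasta", "metadata", "outdir", "fwd_primer", "rev_primer",
        "max_mismatch", "expected_length", "length_tolerance", "enzyme",
        "patterns", "comparison_policy", "match_mode", "gel_min_visible",
        "epsilon", "grouping", "network_label", "seed", "log_level",
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        raw = dict(raw)
        if "enzyme" in raw and isinstance(raw["enzyme"], dict):
            raw["enzyme"] = EnzymeSpec(**raw["enzyme"])
        if "patterns" in raw and isinstance(raw["patterns"], list):
            raw["patterns"] = PatternLibrary(
                [
                    RflpPattern(
                        label=p["label"],
                        cut_positions=frozenset(p["cut_positions"]),
                        amplicon_length=p.get("amplicon_length", 866),
                    )
                    for p in raw["patterns"]
                ]
            )
        if "grouping" in raw:
            raw["grouping"] = tuple(raw["grouping"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["enzyme"] = dataclasses.asdict(self.enzyme)
        d["patterns"] = [
            {"label": p.label, "cut_positions": sorted(p.cut_positions),
             "amplicon_length": p.amplicon_length}
            for p in self.patterns
        ]
        d["grouping"] = list(self.grouping)
        return d


def classify_specimens(
    records: list[SpecimenRecord], config: PipelineConfig
) -> tuple[list[ClassificationResult], dict[str, str], dict[str, str]]:
    """Run extraction + digestion + classification for every specimen.

    Returns (classifications, amplicon sequences by specimen id, failures
    by specimen id with the stage that failed).
    """
    results: list[ClassificationResult] = []
    amplicons: dict[str, str] = {}
    failures: dict[str, str] = {}
    for rec in records:
        try:
            amp = extract_amplicon(
                rec.sequence, config.fwd_primer, config.rev_primer,
                specimen_id=rec.specimen_id, max_mismatch=config.max_mismatch,
                expected_length=config.expected_length,
                tolerance=config.length_tolerance,
            )
        except Exception as exc:  # noqa: BLE001 - stage failure is data, not a bug
            failures[rec.specimen_id] = f"extraction: {exc}"
            continue
        try:
            dig = digest(amp, config.enzyme)
        except Exception as exc:  # noqa: BLE001
            failures[rec.specimen_id] = f"digestion: {exc}"
            continue
        results.append(
            classify_pattern(dig, config.patterns, config.match_mode,
                             config.gel_min_visible)
        )
        amplicons[rec.specimen_id] = amp.sequence
    return results, amplicons, failures


def summarize_composition(
    classifications: list[ClassificationResult],
    metadata: list[SpecimenRecord],
    grouping: tuple[str, ...] = ("region",),
) -> pd.DataFrame:
    """Specimen counts and within-group percentages by metadata keys + label.

    ``unclassified`` appears as its own label row and is never dropped.
    Percentages are computed within each combination of the grouping keys
    and printed to one decimal place in reports.
    """
    for key in grouping:
        if key not in METADATA_FIELDS:
            raise ConfigurationError(
                f"grouping key {key!r} not a metadata field {METADATA_FIELDS}"
            )
    meta_by_id = {m.specimen_id: m for m in metadata}
    rows = []
    for c in classifications:
        m = meta_by_id.get(c.specimen_id)
        if m is None:
            raise DataError(f"classified specimen {c.specimen_id!r} has no metadata")
        row = {k: getattr(m, k) for k in grouping}
        row["label"] = c.label
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*grouping, "label", "count", "percent"])
    df = (
        pd.DataFrame(rows)
        .groupby([*grouping, "label"], sort=True)
        .size()
        .reset_index(name="count")
    )
    if grouping:
        totals = df.groupby(list(grouping))["count"].transform("sum")
    else:
        totals = df["count"].sum()
    df["percent"] = (df["count"] / totals * 100).round(1)
    return df


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory; returns its path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    seqs = read_fasta(config.fasta)
    if not seqs:
        raise DataError("empty input FASTA")
    stubs = read_metadata(config.metadata)
    records = join_sequences_metadata(seqs, stubs)
    stage_counts["input_sequences"] = len(seqs)
    stage_counts["joined_specimens"] = len(records)

    classifications, amplicons, failures = classify_specimens(records, config)
    stage_counts["classified"] = len(classifications)
    stage_counts["failed"] = len(failures)
    assert len(records) == len(classifications) + len(failures), (
        "specimen conservation violated"
    )

    cls_df = pd.DataFrame(
        [
            {
                "specimen_id": c.specimen_id,
                "label": c.label,
                "mode": c.match_mode,
                "distance": c.distance_to_best,
                "runner_up": (f"{c.runner_up[0]}:{c.runner_up[1]}"
                              if c.runner_up else ""),
            }
            for c in classifications
        ]
    )
    cls_df.to_csv(outdir / "classification.tsv", sep="\t", index=False,
                  lineterminator="\n")

    # per-label population genetics over the amplicons
    meta_by_id = {r.specimen_id: r for r in records}
    popgen_report: dict[str, dict] = {}
    groups: dict[str, list[tuple[str, str]]] = {}
    for c in classifications:
        groups.setdefault(c.label, []).append(
            (c.specimen_id, amplicons[c.specimen_id])
        )
    for label, members in sorted(groups.items()):
        entry: dict = {"n": len(members)}
        if len(members) >= 2 and len({len(s) for _, s in members}) == 1:
            stats = diversity_stats(members, config.comparison_policy)
            neut = neutrality_stats(members, config.comparison_policy)
            entry.update(
                h=stats.h, Hd=stats.Hd, Hd_sd=stats.Hd_sd, pi=stats.pi,
                pi_sd=stats.pi_sd, S=stats.S, sites_used=stats.sites_used,
                tajima_d=neut.tajima_d, fu_fs=neut.fu_fs,
                theta_pi=neut.theta_pi, theta_w=neut.theta_w,
                notes=list(stats.notes + neut.notes),
            )
        else:
            entry["notes"] = ["statistics undefined: fewer than 2 comparable sequences"]
        popgen_report[label] = entry
    with open(outdir / "popgen.json", "w", encoding="utf-8") as fh:
        json.dump(popgen_report, fh, indent=2, sort_keys=True)
    pd.DataFrame.from_dict(popgen_report, orient="index").to_csv(
        outdir / "popgen.tsv", sep="\t", lineterminator="\n"
    )

    stage_errors: dict[str, str] = {}

    # median-joining network for the focal label
    focal = config.network_label
    if focal is None and groups:
        focal = max(
            (lbl for lbl in groups if lbl != "unclassified"),
            key=lambda l: (len(groups[l]), l), default=None,
        )
    if focal and focal in groups and len(groups[focal]) >= 1:
        members = groups[focal]
        try:
            table = collapse_haplotypes(members, config.comparison_policy)
            traits = {}
            for hap_id, _seq, mem in table.haplotypes:
                comp: dict[str, int] = {}
                for m in mem:
                    region = meta_by_id[m].region or "unknown"
                    comp[region] = comp.get(region, 0) + 1
                traits[hap_id] = comp
            net = median_joining(
                [seq for _, seq, _ in table.haplotypes],
                list(table.frequencies),
                epsilon=config.epsilon,
                trait_table=traits,
                ids=[hap_id for hap_id, _, _ in table.haplotypes],
            )
            export_network(net, outdir / "network.graphml", "graphml")
            export_network(net, outdir / "network.nex", "nexus")
            export_network(net, outdir / "network_edges.tsv", "tsv")
            stage_counts["network_nodes"] = len(net.nodes)
        except Exception as exc:  # noqa: BLE001 - recorded, pipeline continues
            logger.error("network stage failed for %s: %s", focal, exc)
            stage_errors["network"] = f"label {focal}: {exc}"

    # NJ tree over all distinct haplotypes (all labels pooled)
    all_members = [(sid, seq) for membs in groups.values() for sid, seq in membs]
    if len(all_members) >= 3 and len({len(s) for _, s in all_members}) == 1:
        try:
            table = collapse_haplotypes(all_members, config.comparison_policy)
            if table.h >= 3:
                dm = tn93_matrix(
                    [hap_id for hap_id, _, _ in table.haplotypes],
                    [seq for _, seq, _ in table.haplotypes],
                )
                tree = nj_tree(dm)
                (outdir / "tree.nwk").write_text(write_newick(tree) + "\n",
                                                 encoding="utf-8")
                labels = list(dm.labels)
                pd.DataFrame(dm.values, index=labels, columns=labels).to_csv(
                    outdir / "distances.tsv", sep="\t", lineterminator="\n"
                )
                stage_counts["tree_leaves"] = table.h
        except Exception as exc:  # noqa: BLE001 - recorded, pipeline continues
            logger.error("tree stage failed: %s", exc)
            stage_errors["tree"] = str(exc)

    summary = summarize_composition(classifications, records, config.grouping)
    summary.to_csv(outdir / "composition.tsv", sep="\t", index=False,
                   lineterminator="\n")

    manifest = {
        "package": "coipop",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config.echo(),
        "stage_counts": stage_counts,
        "failures": failures,
        "stage_errors": stage_errors,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failures or stage_errors:
        marks = [f"{k}\t{v}" for k, v in sorted(failures.items())]
        marks += [f"stage:{k}\t{v}" for k, v in sorted(stage_errors.items())]
        (outdir / "FAILED").write_text("\n".join(marks) + "\n", encoding="utf-8")
    return outdir
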