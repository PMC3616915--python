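"""End-to-end orchestration: call -> classify -> features -> orfs -> promoters -> tfbs.

Every stage writes its outputs as flat text (TSV/GFF3/FASTA/JSON) into the
run directory and can be resumed from those intermediates; a resumed run is
bit-identical to a fresh one on the same inputs.  All thresholds are config
values with the pipeline's standard defaults; nothing is hard-coded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import genome_io as gio
from .genome_io import Genome, GeneModel
from .orf_discovery import ORFCall, RBSConfig, discover_orfs
from .promoter_discovery import (
    PromoterHit,
    PromoterSeed,
    SigmaModel,
    TSSAnchor,
    cross_sigma_overlap,
    genome_background,
    run_two_phase,
    string_promoter_search,
)
from .tfbs_analysis import (
    GappedMotifConfig,
    extract_unassigned_upstream,
    scan_gapped_motif,
    write_upstream_fasta,
)
from .tss_calling import TSSCallConfig, TSSContig, call_and_merge
from .tss_classification import (
    ClassifiedTSS,
    MTUConfig,
    RNAFeature,
    build_mtus,
    classify_tss,
    merge_rna_features,
    summarize_classification,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_classified_tsv", "anchors_from_classified"]


def _jsonable(o):
    """json.dump default hook: coerce numpy scalars."""
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    reads: str
    out_dir: str
    priors: str | None = None
    leaders: str | None = None
    promoter_seeds: str | None = None
    seed: int = 0
    call: TSSCallConfig = field(default_factory=TSSCallConfig)
    mtu: MTUConfig = field(default_factory=MTUConfig)
    anti_sd_tail: str | None = None
    rbs_energy_cutoff: float = -3.4535
    sigmas: list[SigmaModel] = field(default_factory=list)
    tfbs: GappedMotifConfig | None = None
    upstream_min_coverage: int = 300

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (("call", TSSCallConfig), ("mtu", MTUConfig), ("tfbs", GappedMotifConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "sigmas" in raw:
            raw["sigmas"] = [SigmaModel(**s) if isinstance(s, dict) else s for s in raw["sigmas"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# intermediate serialization


def contigs_to_frame(contigs: list[TSSContig]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.id,
                c.replicon,
                c.strand,
                c.tss_pos,
                c.end_pos,
                c.read_count,
                ",".join(f"{p}:{n}" for p, n in c.merged_from),
            )
            for c in contigs
        ],
        columns=["id", "replicon", "strand", "tss_pos", "end_pos", "read_count", "merged_from"],
    )


def frame_to_contigs(frame: pd.DataFrame) -> list[TSSContig]:
    out = []
    for row in frame.itertuples(index=False):
        merged = []
        if isinstance(row.merged_from, str) and row.merged_from:
            merged = [
                (int(p), int(n)) for p, n in (kv.split(":") for kv in row.merged_from.split(","))
            ]
        out.append(
            TSSContig(
                id=None if pd.isna(row.id) else str(row.id),
                replicon=str(row.replicon),
                strand=str(row.strand),
                tss_pos=int(row.tss_pos),
                end_pos=int(row.end_pos),
                read_count=int(row.read_count),
                merged_from=merged,
            )
        )
    return out


def classified_to_frame(classified: list[ClassifiedTSS]) -> pd.DataFrame:
    base = contigs_to_frame([c.tss for c in classified])
    base["class"] = [c.tss_class for c in classified]
    base["target"] = [c.target_feature or "" for c in classified]
    base["utr5_len"] = [c.utr5_len if c.utr5_len is not None else -1 for c in classified]
    base["evidence"] = [c.evidence for c in classified]
    return base


def load_classified_tsv(path: str) -> list[ClassifiedTSS]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return _classified_from_frame(frame)


def _classified_from_frame(frame: pd.DataFrame) -> list[ClassifiedTSS]:
    contigs = frame_to_contigs(frame)
    classes = frame["class"].tolist()
    targets = frame["target"].tolist()
    utr5 = frame["utr5_len"].tolist()
    evidence = frame["evidence"].tolist()
    return [
        ClassifiedTSS(
            tss=c,
            tss_class=str(cls),
            target_feature=(str(t) if str(t) else None),
            utr5_len=None if int(u) < 0 else int(u),
            evidence=str(e),
        )
        for c, cls, t, u, e in zip(contigs, classes, targets, utr5, evidence)
    ]


def promoters_to_frame(hits: list[PromoterHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                h.sigma, h.tss_id or "", h.replicon, h.strand, h.pos35, h.seq35,
                h.spacer, h.pos10, h.seq10, h.p35, h.p10, h.gap_to_tss, h.label,
            )
            for h in hits
        ],
        columns=[
            "sigma", "tss_id", "replicon", "strand", "pos35", "seq35", "spacer",
            "pos10", "seq10", "p35", "p10", "gap", "label",
        ],
    )


def orfs_to_frame(orfs: list[ORFCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                o.replicon, o.strand, o.start_codon_pos, o.stop_codon_pos, o.kind,
                o.status, o.name or "", o.tss_id or "",
                o.rbs_energy if o.rbs_energy is not None else "",
                o.leader_seq or "",
            )
            for o in orfs
        ],
        columns=[
            "replicon", "strand", "start_codon_pos", "stop_codon_pos", "kind",
            "status", "name", "tss_id", "rbs_energy", "leader_seq",
        ],
    )


def anchors_from_classified(
    classified: list[ClassifiedTSS], relaxed=None
) -> list[TSSAnchor]:
    anchors = [
        TSSAnchor(
            id=c.tss.id or f"{c.tss.replicon}:{c.tss.tss_pos}",
            replicon=c.tss.replicon,
            strand=c.tss.strand,
            pos=c.tss.tss_pos,
            tss_class=c.tss_class,
        )
        for c in classified
    ]
    for r in relaxed or []:
        anchors.append(
            TSSAnchor(id=r.id or f"relaxed:{r.start}", replicon=r.replicon, strand=r.strand,
                      pos=r.start, tss_class=None)
        )
    return anchors


def load_promoter_seeds(path: str) -> list[PromoterSeed]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return [
        PromoterSeed(
            sigma=str(r.sigma),
            seq35=str(r.seq35),
            spacer_seq=str(r.spacer_seq),
            seq10=str(r.seq10),
            label=str(getattr(r, "label", "model") or "model"),
            tss_id=str(getattr(r, "tss_id", "") or "") or None,
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run all stages in order; returns the machine-readable run report.

    With ``resume=True``, stages whose output files already exist in
    ``out_dir`` are reloaded instead of recomputed.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    genome, genes, reads, priors = gio.load_inputs(
        config.genome, config.annotation, config.reads, config.priors
    )
    report: dict = {"config_hash": config.config_hash(), "stages": {}}

    # --- call
    tss_path = os.path.join(out, "tss.tsv")
    if resume and os.path.exists(tss_path):
        contigs = frame_to_contigs(pd.read_csv(tss_path, sep="\t", keep_default_na=False,
                                               na_values=[]))
        call_report = json.load(open(os.path.join(out, "call_report.json")))
    else:
        contigs, sub, call_report = call_and_merge(reads, config.call)
        contigs_to_frame(contigs).to_csv(tss_path, sep="\t", index=False)
        sub.to_csv(os.path.join(out, "tss_subthreshold.tsv"), sep="\t", index=False)
        json.dump(call_report, open(os.path.join(out, "call_report.json"), "w"), sort_keys=True, default=_jsonable)
        gio.write_gff3(
            [
                (c.replicon, "tssmap", "TSS", c.tss_pos, c.tss_pos, str(c.read_count), c.strand,
                 f"ID={c.id}")
                for c in contigs
            ],
            os.path.join(out, "tss.gff3"),
            genome,
        )
    report["stages"]["call"] = call_report

    # --- classify
    cls_path = os.path.join(out, "classified.tsv")
    leaders = None
    if config.leaders:
        leaders = pd.read_csv(config.leaders, sep="\t")
    mtus = build_mtus(genes, config.mtu, genome)
    if resume and os.path.exists(cls_path):
        classified = _classified_from_frame(
            pd.read_csv(cls_path, sep="\t", keep_default_na=False, na_values=[])
        )
    else:
        classified = classify_tss(contigs, mtus, genome, leaders, config.mtu)
        classified_to_frame(classified).to_csv(cls_path, sep="\t", index=False)

    # --- features
    features = merge_rna_features(classified, genes, config.mtu)
    gio.write_gff3(
        [
            (f.replicon, "tssmap", f.kind, f.lo, f.hi, ".", f.strand,
             f"ID={f.id};target={f.target or '.'}"
             + (f";overlap_region={f.overlap_region}" if f.overlap_region else ""))
            for f in features
        ],
        os.path.join(out, "features.gff3"),
        genome,
    )
    summary = summarize_classification(classified, features, genes, genome)
    json.dump(summary, open(os.path.join(out, "summary.json"), "w"), sort_keys=True, indent=1, default=_jsonable)
    report["stages"]["classify"] = {
        "total_tss": summary["total_tss"],
        "class_counts": summary["class_counts"],
        "n_srna": summary["n_srna"],
        "n_asrna": summary["n_asrna"],
    }

    # --- orfs
    orfs: list[ORFCall] = []
    if config.anti_sd_tail:
        rbs = RBSConfig(anti_sd_tail=config.anti_sd_tail, energy_cutoff=config.rbs_energy_cutoff)
        orfs = discover_orfs([c.tss for c in classified], genome, genes, rbs)
        orfs_to_frame(orfs).to_csv(os.path.join(out, "orfs.tsv"), sep="\t", index=False)
        report["stages"]["orfs"] = {
            "total": len(orfs),
            "new": sum(1 for o in orfs if o.status == "new"),
            "reannotated": sum(1 for o in orfs if o.status == "reannotated"),
        }

    # --- promoters
    promoter_hits: list[PromoterHit] = []
    hit_sets: dict[str, list[PromoterHit]] = {}
    if config.sigmas:
        anchors = anchors_from_classified(classified)
        background = genome_background(genome)
        seeds = load_promoter_seeds(config.promoter_seeds) if config.promoter_seeds else []
        for sigma in config.sigmas:
            if sigma.mode == "string":
                hits = string_promoter_search(sigma, genome, anchors)
            else:
                sigma_seeds = [s for s in seeds if s.sigma == sigma.name]
                if len(sigma_seeds) < 2:
                    continue
                hits = run_two_phase(sigma_seeds, sigma, genome, anchors, background).phase2
            hit_sets[sigma.name] = hits
            promoter_hits.extend(hits)
        promoters_to_frame(promoter_hits).to_csv(
            os.path.join(out, "promoters.tsv"), sep="\t", index=False
        )
        if len(hit_sets) >= 2:
            cross_sigma_overlap(hit_sets).to_csv(
                os.path.join(out, "sigma_overlap.tsv"), sep="\t", index=False
            )
        report["stages"]["promoters"] = {
            s: {
                "total": len(h),
                "labels": {
                    k: int(v)
                    for k, v in sorted(pd.Series([x.label for x in h]).value_counts().items())
                }
                if h
                else {},
            }
            for s, h in sorted(hit_sets.items())
        }

    # --- tfbs + upstream extraction
    if config.tfbs is not None and len(config.tfbs.training_sites) >= 2:
        hits = scan_gapped_motif(genome, genes, config.tfbs)
        pd.DataFrame(
            [(h.motif, h.replicon, h.strand, h.pos, h.score, h.pvalue, h.gene_id) for h in hits],
            columns=["motif", "replicon", "strand", "pos", "score", "pvalue", "gene_id"],
        ).to_csv(os.path.join(out, "tfbs.tsv"), sep="\t", index=False)
        report["stages"]["tfbs"] = {"hits": len(hits)}
    assigned_ids = {h.tss_id for h in promoter_hits if h.tss_id}
    upstream = extract_unassigned_upstream(
        classified, assigned_ids, genome, config.upstream_min_coverage
    )
    write_upstream_fasta(upstream, os.path.join(out, "upstream_unassigned.fasta"))
    report["stages"]["upstream_extract"] = {"sequences": len(upstream)}

    report["partition_ok"] = summary["total_tss"] == sum(summary["class_counts"].values())
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=_jsonable)
    return report
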