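"""End-to-end orchestration: QC -> MOTU -> richness -> community structure.

``run_pipeline`` drives every analysis stage from one RunConfig, writing
delimited reports (QC, MOTU assignments, richness, family, increase,
checklist comparison, ANOSIM, mean dissimilarities), Newick dendrograms
per order x aggregation, and a checksum manifest.  All stochastic stages
derive their streams from the single configured seed, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up
from . import io_formats, sequence_qc, motu as motu_mod, richness as rich, community as comm
from .motu import MotuPartition
from .sequence_qc import QcThresholds

logger = logging.getLogger(__name__)

#: regional checklist reference counts used for the percent-change report
#: (prior-survey species counts per order); overridable in RunConfig.
DEFAULT_CHECKLIST = {"Mesostigmata": 76, "Sarcoptiformes": 144, "Trombidiformes": 122}


@dataclass(frozen=True)
class RunConfig:
    fasta: str
    metadata: str
    out_dir: str
    qc: QcThresholds = QcThresholds()
    threshold: int = motu_mod.DEFAULT_THRESHOLD
    iterations: int = 1000
    permutations: int = 999
    slope_window: int = 10
    min_specimens: int = 100
    min_motus: int = 10
    chao_variant: str = "bias_corrected"
    transform: str = "hellinger"  # for dendrograms; ANOSIM uses raw counts
    systematic_year: Optional[int] = 2010
    checklist: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHECKLIST))
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QcThresholds(**raw.pop("qc", {}))
        return RunConfig(qc=qc, **raw)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "fasta",
                "metadata",
                "out_dir",
                "threshold",
                "iterations",
                "permutations",
                "slope_window",
                "min_specimens",
                "min_motus",
                "chao_variant",
                "transform",
                "systematic_year",
                "seed",
            )
        }
        d["qc"] = {
            "bin_min_length": self.qc.bin_min_length,
            "motu_min_length": self.qc.motu_min_length,
            "max_ambiguous_fraction": self.qc.max_ambiguous_fraction,
        }
        d["checklist"] = dict(self.checklist)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    partition: MotuPartition
    reports: dict[str, pd.DataFrame]
    manifest: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fmt_category(call: rich.CompletenessCall) -> str:
    return call.category.value


def _richness_row(
    label: str,
    motu_labels: Sequence[str],
    config: RunConfig,
    n_families: Optional[int] = None,
) -> dict:
    """One row of the richness report from a group's specimen->MOTU labels."""
    spectrum = rich.AbundanceSpectrum.from_labels(motu_labels, label)
    curve = rich.accumulation_curve(
        motu_labels, iterations=config.iterations, seed=config.seed, group_label=label
    )
    chao = rich.chao1(spectrum, config.chao_variant)
    row = {
        "group": label,
        "motus": spectrum.S_obs,
        "n": spectrum.N,
        "chao": round_half_up(chao.estimate),
        "chao_se": round_half_up(chao.se),
        "terminal_slope": np.nan,
        "category": "",
    }
    if n_families is not None:
        row["n_families"] = n_families
    if spectrum.N > config.slope_window:
        call = rich.terminal_slope(curve, config.slope_window)
        row["terminal_slope"] = round_half_up(call.terminal_slope, 3)
        row["category"] = _fmt_category(call)
    return row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages on one dataset and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    stage = "load"
    try:
        seqs = io_formats.read_fasta(config.fasta)
        metadata = io_formats.read_metadata(config.metadata)
        meta_by_id = {m.specimen_id: m for m in metadata}

        # --- QC -------------------------------------------------------
        stage = "qc"
        recovered_ids = {s.specimen_id for s in seqs}
        motu_grade = [s for s in seqs if sequence_qc.passes_motu_grade(s, config.qc)]
        bin_grade_ids = {
            s.specimen_id for s in seqs if sequence_qc.passes_bin_grade(s, config.qc)
        }
        summary = sequence_qc.summarize_success(metadata, recovered_ids, "order")
        qc_rows = []
        for group, (attempted, recovered) in sorted(summary.per_group.items()):
            grp_seqs = [
                s for s in seqs if meta_by_id[s.specimen_id].order == group
            ]
            qc_rows.append(
                {
                    "order": group,
                    "attempted": attempted,
                    "recovered": recovered,
                    "success_pct": round_half_up(100.0 * recovered / attempted, 1),
                    "motu_grade": sum(
                        sequence_qc.passes_motu_grade(s, config.qc) for s in grp_seqs
                    ),
                    "bin_grade": sum(
                        sequence_qc.passes_bin_grade(s, config.qc) for s in grp_seqs
                    ),
                }
            )
        qc_rows.append(
            {
                "order": "Total",
                "attempted": summary.attempted,
                "recovered": summary.recovered,
                "success_pct": summary.rate_pct,
                "motu_grade": len(motu_grade),
                "bin_grade": len(bin_grade_ids),
            }
        )
        qc_report = pd.DataFrame(qc_rows)
        if len(summary.per_group) >= 2:
            homo = sequence_qc.success_homogeneity_test(summary.per_group)
            (out / "qc_homogeneity.json").write_text(
                json.dumps(
                    {
                        "statistic": round(homo.statistic, 3),
                        "df": homo.df,
                        "p": float(f"{homo.p:.3g}"),
                        "warning": homo.warning,
                    },
                    indent=1,
                )
            )
        logger.info(
            "qc: %d attempted, %d recovered, %d MOTU-grade",
            summary.attempted,
            summary.recovered,
            len(motu_grade),
        )

        # --- MOTU clustering -----------------------------------------
        stage = "cluster"
        partition = motu_mod.delineate_motus(motu_grade, config.threshold)
        assign = pd.DataFrame(
            {
                "specimen_id": list(partition.assignment),
                "motu_label": list(partition.assignment.values()),
            }
        )
        sizes = assign["motu_label"].value_counts()
        assign["motu_size"] = assign["motu_label"].map(sizes)
        motu_table = motu_mod.motu_summary(partition, metadata)

        # --- richness -------------------------------------------------
        stage = "richness"
        order_of = {m.specimen_id: m.order for m in metadata}
        family_of = {m.specimen_id: m.family for m in metadata}
        per_order: dict[str, list[str]] = {}
        for sid, lab in partition.assignment.items():
            per_order.setdefault(order_of[sid], []).append(lab)
        richness_rows = []
        orders = sorted(per_order)
        for o in orders:
            fams = {family_of[s] for s in partition.assignment if order_of[s] == o}
            richness_rows.append(_richness_row(o, per_order[o], config, len(fams)))
        all_labels = [partition.assignment[s] for s in partition.assignment]
        total_fams = {family_of[s] for s in partition.assignment}
        total_row = _richness_row("Total", all_labels, config, len(total_fams))
        richness_rows.append(total_row)
        richness_report = pd.DataFrame(richness_rows)
        per_order_sum = sum(r["motus"] for r in richness_rows[:-1])
        if per_order_sum != total_row["motus"]:  # pragma: no cover - guard
            raise AssertionError("per-order MOTU counts do not sum to the total")

        # family-level report with "Others" pooling
        groups = rich.group_for_analysis(
            metadata, partition, config.min_specimens, config.min_motus
        )
        fam_rows = []
        for g in sorted(groups, key=lambda g: (g.order, g.pooled, g.label)):
            labels = [partition.assignment[s] for s in g.specimen_ids]
            row = _richness_row(f"{g.order}/{g.label}", labels, config)
            row.pop("chao", None)
            row.pop("chao_se", None)
            fam_rows.append(row)
        family_report = pd.DataFrame(fam_rows)

        # --- increase accounting (systematic core vs full survey) ----
        stage = "increase"
        increase_report = pd.DataFrame()
        if config.systematic_year is not None:
            core_ids = {
                s
                for s in partition.assignment
                if meta_by_id[s].year == config.systematic_year
            }
            if core_ids and len(core_ids) < len(partition.assignment):
                inc_rows = []
                for o in orders + ["Total"]:
                    sel = (
                        (lambda s: order_of[s] == o)
                        if o != "Total"
                        else (lambda s: True)
                    )
                    aug = {partition.assignment[s] for s in partition.assignment if sel(s)}
                    core = {partition.assignment[s] for s in core_ids if sel(s)}
                    # MOTUs seen only outside the core must not count as core
                    core &= aug
                    inc = rich.richness_increase(core, aug)
                    row = {
                        "group": o,
                        "additional_motus": inc.additional,
                        "pct_increase": inc.percent_rounded,
                    }
                    aug_labels = [
                        partition.assignment[s] for s in partition.assignment if sel(s)
                    ]
                    core_labels = [partition.assignment[s] for s in core_ids if sel(s)]
                    if core_labels:
                        chao_aug = rich.chao1(
                            rich.AbundanceSpectrum.from_labels(aug_labels),
                            config.chao_variant,
                        ).estimate
                        chao_core = rich.chao1(
                            rich.AbundanceSpectrum.from_labels(core_labels),
                            config.chao_variant,
                        ).estimate
                        row["additional_chao"] = round_half_up(chao_aug - chao_core)
                        row["chao_pct_increase"] = rich.percent_change(
                            chao_aug, chao_core
                        )
                    inc_rows.append(row)
                increase_report = pd.DataFrame(inc_rows)

        # --- checklist comparison ------------------------------------
        check_rows = []
        for o in orders:
            ref = config.checklist.get(o)
            if ref:
                new = len(set(per_order[o]))
                check_rows.append(
                    {
                        "order": o,
                        "motus": new,
                        "reference_species": ref,
                        "pct_change": rich.percent_change(new, ref),
                    }
                )
        checklist_report = pd.DataFrame(check_rows)

        # --- community structure --------------------------------------
        stage = "community"
        anosim_rows = []
        meandis_rows = []
        for o in orders:
            order_meta = [m for m in metadata if m.order == o]
            for aggregate_by in ("site", "substrate"):
                cm = comm.build_matrix(
                    order_meta,
                    partition,
                    aggregate_by,
                    year=config.systematic_year,
                )
                if len(cm.unit_labels) < 2:
                    continue
                mat = comm.hellinger(cm) if config.transform == "hellinger" else cm
                dm = comm.pairwise_bray_curtis(mat)
                dend = comm.complete_linkage(dm)
                io_formats.write_newick(
                    dend, out / f"dendrogram_{o}_{aggregate_by}.nwk"
                )
                raw_dm = comm.pairwise_bray_curtis(cm)
                meandis_rows.append(
                    {
                        "order": o,
                        "aggregation": aggregate_by,
                        "mean_bray_curtis": round_half_up(
                            comm.mean_dissimilarity(raw_dm), 2
                        ),
                    }
                )
                if aggregate_by == "site" and cm.grouping:
                    sizes_ok = (
                        pd.Series(list(cm.grouping.values())).value_counts().min() >= 2
                        and len(set(cm.grouping.values())) >= 2
                    )
                    if sizes_ok:
                        res = comm.anosim(
                            raw_dm,
                            cm.grouping,
                            n_permutations=config.permutations,
                            seed=config.seed,
                        )
                        anosim_rows.append(
                            {
                                "order": o,
                                "aggregation": aggregate_by,
                                "R": round(res.R, 3),
                                "p": float(f"{res.p:.3g}"),
                                "n_permutations": res.n_permutations,
                                "seed": res.seed,
                            }
                        )
        anosim_report = pd.DataFrame(anosim_rows)
        meandis_report = pd.DataFrame(meandis_rows)

        # --- write reports + manifest ---------------------------------
        stage = "write"
        reports = {
            "qc_report": qc_report,
            "motu_assignments": assign,
            "motu_summary": motu_table,
            "richness_report": richness_report,
            "family_report": family_report,
            "increase_report": increase_report,
            "checklist_comparison": checklist_report,
            "anosim_report": anosim_report,
            "mean_dissimilarity": meandis_report,
        }
        for name, df in reports.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        files = sorted(p for p in out.iterdir() if p.name != "manifest.tsv")
        manifest = pd.DataFrame(
            {"file": [p.name for p in files], "sha256": [_sha256(p) for p in files]}
        )
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
        return PipelineResult(out, partition, reports, manifest)
    except Exception as e:
        (out / "FAILED").write_text(f"stage={stage}: {e}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def compare_runs(core: PipelineResult, augmented: PipelineResult) -> pd.DataFrame:
    """Increase accounting between two separate runs (count differencing).

    Both runs must have used the same clustering threshold and QC bounds
    (checked from their serialized configs).  MOTU labels are run-local, so
    the comparison differences per-group MOTU counts and Chao estimates
    rather than intersecting label sets; within a single run,
    ``run_pipeline`` computes the subset-exact version instead.
    """
    cfg_a = yaml.safe_load((core.out_dir / "run_config.yaml").read_text())
    cfg_b = yaml.safe_load((augmented.out_dir / "run_config.yaml").read_text())
    for key in ("threshold", "qc"):
        if cfg_a[key] != cfg_b[key]:
            raise ValueError(
                f"runs differ in {key!r} ({cfg_a[key]} vs {cfg_b[key]}); "
                "re-run with matching settings before comparing"
            )
    a = core.reports["richness_report"].set_index("group")
    b = augmented.reports["richness_report"].set_index("group")
    rows = []
    for group in b.index:
        if group not in a.index:
            continue
        add = int(b.loc[group, "motus"] - a.loc[group, "motus"])
        pct = rich.percent_change(b.loc[group, "motus"], a.loc[group, "motus"])
        add_chao = round_half_up(b.loc[group, "chao"] - a.loc[group, "chao"])
        pct_chao = rich.percent_change(b.loc[group, "chao"], a.loc[group, "chao"])
        rows.append(
            {
                "group": group,
                "additional_motus": add,
                "pct_increase": pct,
                "additional_chao": add_chao,
                "chao_pct_increase": pct_chao,
            }
        )
    return pd.DataFrame(rows)
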