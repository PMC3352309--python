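"""End-to-end orchestration: collapse -> orthologs -> Ks -> families ->
events -> peaks -> times (+ optional enrichment), with per-stage TSV dumps
and a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import families as fam_mod
from . import homology, ks as ks_mod, peaks as peaks_mod, redundancy
from .peaks import ClockRate, KsDistribution
from .seq_io import SequenceRecord, read_fasta, write_fasta, write_table

log = logging.getLogger("paleoploid")


@dataclass
class PipelineConfig:
    """Every stage threshold, serializable and round-trippable."""

    min_block: int = 100
    min_identity: float = 1.0
    rbh_evalue: float = 1e-20
    rbh_min_aligned: int = 300
    paralog_coverage: float = 0.70
    paralog_evalue: float = 1e-10
    min_aa: int = 30
    max_ks: float = 2.0
    bin_width: float = 0.01
    bandwidth: float = 0.01  # event-distribution kernel; resolves recent bursts
    ortholog_bandwidth: float | None = None  # None = Scott's rule (unimodal)
    min_prominence_frac: float = 0.05
    min_peak_values: int = 50
    rate: float = 3.51e-9
    convention: str = "direct"
    ks_method: str = "ng86"
    seed: int = 0

    @property
    def clock(self) -> ClockRate:
        return ClockRate(self.rate, self.convention)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SetResult:
    """Paranome analysis of one sequence set."""

    label: str
    n_input: int
    n_retained: int
    n_redundant_pairs: int
    paralog_pairs: list = field(repr=False, default_factory=list)
    families: list = field(repr=False, default_factory=list)
    event_summary: dict = field(default_factory=dict)
    event_dist: KsDistribution | None = None
    duplication_mode_ks: float | None = None
    duplication_time_mya: float | None = None
    has_secondary_peak: bool = False

    @property
    def n_paralog_sequences(self) -> int:
        ids = {p.id_a for p in self.paralog_pairs} | {
            p.id_b for p in self.paralog_pairs
        }
        return len(ids)

    @property
    def paralog_percentage(self) -> float:
        if not self.n_retained:
            return 0.0
        return 100.0 * self.n_paralog_sequences / self.n_retained


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - named-stage abort contract
        raise StageError(name, exc) from exc
    log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
    return out


def collapse_set(
    records: Sequence[SequenceRecord], cfg: PipelineConfig
) -> tuple[list[SequenceRecord], dict[str, str], int]:
    pairs = redundancy.find_redundant_pairs(
        records, cfg.min_block, cfg.min_identity
    )
    retained, mapping = redundancy.collapse(records, pairs)
    return retained, mapping, len(pairs)


def ortholog_analysis(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    cfg: PipelineConfig,
) -> tuple[list, list[ks_mod.PairKs], KsDistribution]:
    """RBH orthologs, their Ks, and the filtered ortholog Ks distribution."""
    pairs = homology.find_orthologs(
        set_a, set_b, cfg.rbh_evalue, cfg.rbh_min_aligned
    )
    by_id_a = {r.id: r for r in set_a}
    by_id_b = {r.id: r for r in set_b}
    estimates: list[ks_mod.PairKs] = []
    for p in pairs:
        res = ks_mod.ks_for_pair(
            by_id_a[p.id_a], by_id_b[p.id_b], cfg.ks_method,
            precomputed_local=p.alignment,
        )
        if res is not None:
            p.ks = res.estimate.ks
            p.ka = res.estimate.ka
            p.saturated = res.estimate.saturated
            p.aligned_aa = res.aligned_aa
            estimates.append(res)
    kept = ks_mod.filter_pairs(estimates, cfg.min_aa, cfg.max_ks)
    dist = peaks_mod.make_histogram(
        [p.estimate.ks for p in kept], cfg.bin_width, cfg.max_ks, kind="ortholog"
    )
    if len(dist.values) >= cfg.min_peak_values:
        peaks_mod.detect_peaks(
            dist, cfg.ortholog_bandwidth, cfg.min_prominence_frac, cfg.min_peak_values
        )
    else:
        log.warning(
            "only %d filtered ortholog Ks values; skipping mode detection",
            len(dist.values),
        )
    return pairs, kept, dist


def paranome_analysis(
    records: Sequence[SequenceRecord], cfg: PipelineConfig, label: str
) -> tuple[SetResult, list[SequenceRecord]]:
    """Collapse, paralog detection, families, event dating, peak verdict.

    Returns the per-set result and the retained (collapsed) records.
    """
    retained, _, n_red = _stage(
        f"collapse[{label}]", collapse_set, records, cfg
    )
    result = SetResult(
        label=label,
        n_input=len(records),
        n_retained=len(retained),
        n_redundant_pairs=n_red,
    )
    paralog_pairs = _stage(
        f"paralogs[{label}]",
        homology.find_paralogs,
        retained,
        cfg.paralog_coverage,
        cfg.paralog_evalue,
    )
    result.paralog_pairs = paralog_pairs
    families = homology.build_families(paralog_pairs)
    by_id = {r.id: r for r in retained}
    for fam in families:
        _stage(
            f"date[{label}:{fam.family_id}]",
            fam_mod.date_family,
            fam, by_id, cfg.ks_method, cfg.min_aa,
        )
    result.families = families
    event_ks, summary = fam_mod.collect_events(families, cfg.max_ks)
    result.event_summary = summary
    dist = peaks_mod.make_histogram(event_ks, cfg.bin_width, cfg.max_ks)
    result.event_dist = dist
    if len(event_ks) >= cfg.min_peak_values:
        peaks_mod.detect_peaks(
            dist, cfg.bandwidth, cfg.min_prominence_frac, cfg.min_peak_values
        )
        mode = peaks_mod.duplication_mode(dist, cfg.bandwidth)
        if mode is not None:
            result.has_secondary_peak = True
            result.duplication_mode_ks = mode.location
            result.duplication_time_mya = peaks_mod.ks_to_mya(
                mode.location, cfg.clock
            )
    return result, retained


def run_pipeline(
    config: PipelineConfig,
    set_a: Sequence[SequenceRecord] | str | Path,
    set_b: Sequence[SequenceRecord] | str | Path | None = None,
    out_dir: str | Path | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> dict:
    """Run the full analysis and return the JSON-ready report.

    ``set_a``/``set_b`` are sequence collections or FASTA paths; with
    ``out_dir`` every intermediate table is written so any stage can be
    re-run independently.
    """
    if isinstance(set_a, (str, Path)):
        set_a = _stage("collapse", read_fasta, set_a)
    if isinstance(set_b, (str, Path)):
        set_b = _stage("collapse", read_fasta, set_b)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": asdict(config), "sets": {}, "speciation": None}
    results: list[SetResult] = []
    collapsed: dict[str, list[SequenceRecord]] = {}
    for label, records in ((label_a, set_a), (label_b, set_b)):
        if records is None:
            continue
        res, retained = paranome_analysis(records, config, label)
        results.append(res)
        collapsed[label] = retained
        report["sets"][label] = {
            "sequences_in": res.n_input,
            "sequences_retained": res.n_retained,
            "redundant_pairs": res.n_redundant_pairs,
            "paralog_pairs": len(res.paralog_pairs),
            "paralog_sequences": res.n_paralog_sequences,
            "paralog_percentage": round(res.paralog_percentage, 1),
            "gene_families": len(res.families),
            "family_members": sum(len(f.member_ids) for f in res.families),
            **res.event_summary,
            "has_secondary_peak": res.has_secondary_peak,
            "duplication_mode_ks": res.duplication_mode_ks,
            "duplication_time_mya": res.duplication_time_mya,
        }
        if out is not None:
            _dump_set(res, collapsed[label], out)

    if set_b is not None:
        ortho_pairs, kept, dist = _stage(
            "orthologs",
            ortholog_analysis,
            collapsed[label_a],
            collapsed[label_b],
            config,
        )
        mode = peaks_mod.primary_mode(dist)
        report["speciation"] = {
            "ortholog_pairs": len(ortho_pairs),
            "ortholog_pairs_filtered": len(kept),
            "ks_mode": mode.location if mode else None,
            "time_mya": peaks_mod.ks_to_mya(mode.location, config.clock)
            if mode
            else None,
        }
        if out is not None:
            write_table(
                pd.DataFrame(
                    {
                        "id_a": [p.id_a for p in ortho_pairs],
                        "id_b": [p.id_b for p in ortho_pairs],
                        "aligned_nt": [p.aligned_nt for p in ortho_pairs],
                        "evalue": [p.evalue for p in ortho_pairs],
                        "ks": [p.ks for p in ortho_pairs],
                        "ka": [p.ka for p in ortho_pairs],
                    }
                ),
                out / "orthologs.tsv",
            )

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")
    return report


def _dump_set(res: SetResult, retained: Sequence[SequenceRecord], out: Path) -> None:
    label = res.label
    write_fasta(retained, out / f"retained_{label}.fa")
    write_table(
        pd.DataFrame(
            {
                "id_a": [p.id_a for p in res.paralog_pairs],
                "id_b": [p.id_b for p in res.paralog_pairs],
                "coverage_shorter": [p.coverage_shorter for p in res.paralog_pairs],
                "evalue": [p.evalue for p in res.paralog_pairs],
            }
        ),
        out / f"paralogs_{label}.tsv",
    )
    fam_rows = [
        {"family_id": f.family_id, "member_id": m}
        for f in res.families
        for m in f.member_ids
    ]
    write_table(pd.DataFrame(fam_rows), out / f"families_{label}.tsv")
    ev_rows = [
        {"family_id": f.family_id, "event_ks": k if k is not None else ""}
        for f in res.families
        for k in f.event_ks
    ]
    write_table(pd.DataFrame(ev_rows), out / f"events_{label}.tsv")
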