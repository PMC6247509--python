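"""Run configuration and the end-to-end evaluation pipeline:
screen single primers -> build pairs -> evaluate against the criteria ->
rank, writing one TSV per stage plus a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .blockers import BlockerParams
from .design import DesignParams
from .io import config_hash, pct, write_coverage_tsv, write_tsv
from .oligo import Oligo, TmParams, round_tm
from .pairs import VariableRegionMap, enumerate_pairs
from .pcr import pair_coverage, primer_coverage
from .reference import ReferenceDB
from .screening import (
    PairEvaluation,
    Thresholds,
    biodiversity_criteria,
    rank_pairs,
    screen_single_primers,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    tm_params: TmParams = field(default_factory=TmParams)
    region_map: VariableRegionMap = field(default_factory=VariableRegionMap)
    blocker_params: BlockerParams = field(default_factory=BlockerParams)
    design_params: DesignParams = field(default_factory=DesignParams)
    max_tm_diff: float = 5.0
    mismatch_levels: tuple[int, ...] = (0, 1)
    seed: int = 0
    output_dir: Path = Path("mycoprimer_out")

    def to_dict(self) -> dict:
        d = {
            "thresholds": dataclasses.asdict(self.thresholds),
            "tm_params": dataclasses.asdict(self.tm_params),
            "region_map": {
                k: list(v) for k, v in self.region_map.regions.items()
            },
            "blocker_params": dataclasses.asdict(self.blocker_params),
            "design_params": dataclasses.asdict(self.design_params),
            "max_tm_diff": self.max_tm_diff,
            "mismatch_levels": list(self.mismatch_levels),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "thresholds" in d:
            t = dict(d["thresholds"])
            if "focus_groups" in t:
                t["focus_groups"] = tuple(t["focus_groups"])
            kw["thresholds"] = Thresholds(**t)
        if "tm_params" in d:
            kw["tm_params"] = TmParams(**d["tm_params"])
        if "region_map" in d:
            kw["region_map"] = VariableRegionMap(
                {k: tuple(v) for k, v in d["region_map"].items()}
            )
        if "blocker_params" in d:
            kw["blocker_params"] = BlockerParams(**d["blocker_params"])
        if "design_params" in d:
            kw["design_params"] = DesignParams(**d["design_params"])
        for key in ("max_tm_diff", "seed"):
            if key in d:
                kw[key] = d[key]
        if "mismatch_levels" in d:
            kw["mismatch_levels"] = tuple(d["mismatch_levels"])
        if "output_dir" in d:
            kw["output_dir"] = Path(d["output_dir"])
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(
    config: RunConfig,
    db: ReferenceDB,
    primers: Sequence[Oligo],
) -> dict:
    """Execute screen -> pair -> evaluate -> rank and write stage outputs.

    Returns the summary dict (also written as JSON).  Any stage error is
    re-raised with the stage name; nothing is written before the inputs
    validate, so failures leave no partial outputs.
    """
    if not primers:
        raise PipelineError("input", "empty primer list")
    if not len(db):
        raise PipelineError("input", "empty reference database")
    outdir = Path(config.output_dir)
    # hash only the scientific configuration, not where the output lands
    hashable = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    meta = {"config": config_hash(hashable), "seed": config.seed}
    levels = config.mismatch_levels

    try:
        reports = [primer_coverage(p, db, levels) for p in primers]
        retained = screen_single_primers(reports, config.thresholds)
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc
    retained_names = {r.query_label for r in retained}
    kept_primers = [p for p in primers if p.name in retained_names]

    try:
        pairs = enumerate_pairs(kept_primers, config.max_tm_diff, config.region_map)
    except Exception as exc:
        raise PipelineError("pairs", str(exc)) from exc

    evaluations: list[PairEvaluation] = []
    try:
        for pair in pairs:
            report = pair_coverage(pair, db, levels)
            ev = PairEvaluation(pair=pair, report=report)
            biodiversity_criteria(ev, config.thresholds)
            evaluations.append(ev)
        ranked = rank_pairs(evaluations, config.thresholds)
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    outdir.mkdir(parents=True, exist_ok=True)
    write_coverage_tsv(reports, outdir / "primer_coverage.tsv", meta)
    screen_rows = [
        {
            "name": rep.query_label,
            "fungal_cov_1m_percent": pct(rep.fungal_coverage(1)),
            "retained": rep.query_label in retained_names,
        }
        for rep in reports
    ]
    write_tsv(pd.DataFrame(screen_rows), outdir / "screen.tsv", meta)

    pair_rows = [
        {
            "forward": p.forward.name, "reverse": p.reverse.name,
            "tm_diff": round_tm(p.tm_difference),
            "amplicon_nt": p.expected_amplicon_nt if p.geometry_known else "",
            "size_group": p.size_group or "",
            "regions": ",".join(f"{r}:{c}" for r, c in p.regions),
        }
        for p in pairs
    ]
    write_tsv(pd.DataFrame(pair_rows), outdir / "pairs.tsv", meta)

    rank_rows = []
    for rank, ev in enumerate(ranked, start=1):
        rep, flags = ev.report, ev.flags
        rank_rows.append(
            {
                "rank": rank, "pair": ev.name,
                "size_group": ev.pair.size_group or "",
                "fungal_cov_0m_percent": pct(rep.fungal_coverage(0)),
                "fungal_cov_1m_percent": pct(rep.fungal_coverage(1)),
                "coamp_0m_percent": pct(rep.co_amplification(0)),
                "coamp_1m_percent": pct(rep.co_amplification(1)),
                "focus_coamp_0m_percent": pct(
                    ev.focus_coamp(config.thresholds.focus_groups, 0)
                ),
                "cov0_ok": flags.cov0_ok, "cov1_ok": flags.cov1_ok,
                "all_groups_hit": flags.all_groups_hit,
                "coamp_ok": flags.coamp_ok, "passed": flags.passed,
                "missing_groups": ",".join(ev.missing_groups),
            }
        )
    write_tsv(pd.DataFrame(rank_rows), outdir / "ranking.tsv", meta)

    summary = {
        "n_primers": len(primers),
        "n_primers_retained": len(kept_primers),
        "n_pairs": len(pairs),
        "n_pairs_passing": sum(1 for ev in evaluations if ev.flags.passed),
        "top_pair": ranked[0].name if ranked else None,
        "seed": config.seed,
        "config_hash": meta["config"],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
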