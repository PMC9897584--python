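"""End-to-end orchestration of the annotation-transfer pipeline.

Stage 1: parse forward (model -> target) hit tables, filter, take top
hits, invert into non-redundant target groups; optionally parse reverse
(target -> model) tables and intersect into best-bidirectional pairs.
Outputs are deterministic tab-separated tables plus a stage-count
summary; re-running on unchanged inputs is byte-identical.

Judgment calls the method leaves to a domain expert (e.g. the final
call on which pocket-passing candidates are functional) are surfaced as
report flags, never decided silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import homology_map as hm
from .io_formats import HitTable, parse_hhr

log = logging.getLogger("homolot")


@dataclass
class PipelineConfig:
    forward_dir: str
    reverse_dir: str | None = None
    out_dir: str = "homolot_out"
    evalue_max: float = 1e-3
    probability_min: float = 20.0
    max_hits: int = 250
    probability_select: float = 100.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_config(self) -> hm.FilterConfig:
        return hm.FilterConfig(
            evalue_max=self.evalue_max,
            probability_min=self.probability_min,
            max_hits=self.max_hits,
            probability_select=self.probability_select,
        )


def load_hit_tables(directory: str | Path, suffix: str = ".hhr") -> list[HitTable]:
    """Parse every hit-table file in a directory, in sorted name order."""
    tables = []
    for path in sorted(Path(directory).glob(f"*{suffix}")):
        with open(path) as fh:
            tables.append(parse_hhr(fh))
    return tables


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run stage 1 end-to-end and write per-stage TSV outputs.

    Returns the summary dict (counts per stage).  Every output row
    carries the input ids that produced it.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fcfg = cfg.filter_config()

    forward_tables = load_hit_tables(cfg.forward_dir)
    log.info("parsed %d forward hit tables", len(forward_tables))
    forward_top = hm.top_hits(forward_tables, fcfg)
    map_rows = [
        {
            "query_id": q,
            "target_id": h.target_id,
            "probability": h.probability,
            "evalue": h.evalue,
            "score": h.score,
            "cols_matched": h.cols_matched,
        }
        for q, h in sorted(forward_top.entries.items())
    ]
    pd.DataFrame(
        map_rows,
        columns=["query_id", "target_id", "probability", "evalue", "score", "cols_matched"],
    ).to_csv(out / "map.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"query_id": sorted(forward_top.unmapped)}
    ).to_csv(out / "unmapped.tsv", sep="\t", index=False)

    nrm = hm.nonredundant_targets(forward_top)
    group_rows = [
        {"target_id": t, "n_queries": len(qs), "query_ids": ",".join(sorted(qs))}
        for t, qs in sorted(nrm.groups.items())
    ]
    pd.DataFrame(
        group_rows, columns=["target_id", "n_queries", "query_ids"]
    ).to_csv(out / "nonredundant.tsv", sep="\t", index=False)

    summary = {
        "queries_in": len(forward_tables),
        "queries_mapped": len(forward_top.entries),
        "queries_unmapped": len(forward_top.unmapped),
        "unique_targets": len(nrm.groups),
        "bbh_pairs": 0,
    }

    if cfg.reverse_dir:
        reverse_tables = load_hit_tables(cfg.reverse_dir)
        log.info("parsed %d reverse hit tables", len(reverse_tables))
        reverse_top = hm.top_hits(reverse_tables, fcfg)
        pairs = hm.bidirectional_best(forward_top, reverse_top)
        pd.DataFrame(
            [
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "forward_probability": p.forward_hit.probability,
                    "reverse_probability": p.reverse_hit.probability,
                }
                for p in pairs
            ],
            columns=["id_a", "id_b", "forward_probability", "reverse_probability"],
        ).to_csv(out / "bbh.tsv", sep="\t", index=False)
        summary["bbh_pairs"] = len(pairs)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    log.info("summary: %s", summary)
    return summary
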