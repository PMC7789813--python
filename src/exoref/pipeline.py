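"""End-to-end orchestration: normalize -> screen -> stability -> combos -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

import exoref
from exoref.expression_io import (
    CtTable,
    ExpressionMatrix,
    GeneLengthTable,
    SampleDesign,
    ValidationError,
    compute_cpm,
    compute_tpm,
    ct_to_abundance,
    read_ct_table,
    read_design,
    read_lengths,
    read_matrix,
)
from exoref.screening import screen
from exoref.stability import (
    ComboStability,
    av_combination,
    cv_stability,
    m_values,
    normfinder_stability,
    rank_candidates,
)

logger = logging.getLogger(__name__)

MODE_DEFAULTS = {
    "mRNA": {"top_n": 10, "combo_sizes": [3], "normalization": "TPM"},
    "miRNA": {"top_n": 6, "combo_sizes": [2], "normalization": "CPM"},
    "qPCR": {"top_n": None, "combo_sizes": [3], "normalization": "abundance"},
}


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    mode: str = "mRNA"
    counts: str | None = None
    lengths: str | None = None
    ct: str | None = None
    design: str | None = None
    p_threshold: float = 0.1
    top_n: int | None = None
    combo_sizes: list[int] = field(default_factory=list)
    scorers: list[str] = field(default_factory=lambda: ["cv", "m"])
    combo_strategy: str = "rank-blocks"
    pseudocount: float = 1.0
    seed: int = 0
    out_dir: str = "exoref_out"

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValidationError(f"mode must be one of {sorted(MODE_DEFAULTS)}, got {self.mode!r}")
        if not (0.0 <= self.p_threshold <= 1.0):
            raise ValidationError("p_threshold must lie in [0, 1]")
        if self.top_n is None:
            self.top_n = MODE_DEFAULTS[self.mode]["top_n"]
        if not self.combo_sizes:
            self.combo_sizes = list(MODE_DEFAULTS[self.mode]["combo_sizes"])
        if any(k < 2 for k in self.combo_sizes):
            raise ValidationError("combo sizes must be >= 2")
        bad = set(self.scorers) - {"cv", "m", "normfinder"}
        if bad:
            raise ValidationError(f"unknown scorers: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """Stage counts, the stability table, ranked combos, warnings, manifest."""

    stage_counts: dict[str, int]
    candidates: list[str]
    stability: pd.DataFrame | None
    combos: list[ComboStability]
    warnings: list[str]
    manifest: dict

    def to_json(self) -> str:
        payload = {
            "stage_counts": self.stage_counts,
            "candidates": self.candidates,
            "stability": None
            if self.stability is None
            else self.stability.reset_index().to_dict(orient="records"),
            "combos": [{"members": list(c.members), "av": c.av} for c in self.combos],
            "warnings": self.warnings,
            "manifest": self.manifest,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def evaluate_combos(
    stability: pd.DataFrame,
    combo_size: int,
    strategy: str = "rank-blocks",
) -> list[ComboStability]:
    """Score reference-feature combinations by the geometric mean of M.

    ``rank-blocks`` forms consecutive blocks of the final ranking
    (1..k, k+1..2k, ...; a trailing partial block smaller than 2 is
    dropped); ``exhaustive`` scores every size-k subset. Both return
    combos sorted by ascending AV (ties by member tuple).
    """
    if combo_size < 2:
        raise ValidationError("combo_size must be >= 2")
    ordered = stability.sort_values("final_rank")
    feats = ordered.index.tolist()
    if combo_size > len(feats):
        raise ValidationError(f"combo_size {combo_size} exceeds candidate count {len(feats)}")
    m = ordered["m"]
    if strategy == "rank-blocks":
        blocks = [
            tuple(feats[i : i + combo_size]) for i in range(0, len(feats), combo_size)
        ]
        blocks = [b for b in blocks if len(b) >= 2]
        combos = [av_combination(m, b) for b in blocks]
    elif strategy == "exhaustive":
        combos = [av_combination(m, c) for c in combinations(feats, combo_size)]
    else:
        raise ValidationError(f"unknown combo strategy {strategy!r}")
    return sorted(combos, key=lambda c: (c.av, c.members))


def _normalize(config: PipelineConfig, counts: ExpressionMatrix,
               lengths: GeneLengthTable | None) -> ExpressionMatrix:
    if config.mode == "mRNA":
        if lengths is None:
            raise ValidationError("mRNA mode requires a gene-length table for TPM")
        return compute_tpm(counts, lengths)
    return compute_cpm(counts)


def run_pipeline(
    config: PipelineConfig,
    *,
    counts: ExpressionMatrix | None = None,
    design: SampleDesign | None = None,
    lengths: GeneLengthTable | None = None,
    ct: CtTable | None = None,
    write_outputs: bool = False,
) -> RunReport:
    """Execute the full analysis and return (optionally write) the report.

    Inputs may be passed in memory or read from the paths in ``config``.
    qPCR mode skips the count-based screening cascade and scores stability
    on 2^-Ct abundances directly; deterministic for fixed config + inputs.
    """
    warnings: list[str] = []
    manifest = {"config": asdict(config), "version": exoref.__version__}

    if design is None and config.design:
        design = read_design(config.design)

    if config.mode == "qPCR":
        if ct is None:
            if not config.ct:
                raise ValidationError("qPCR mode requires a Ct table")
            ct = read_ct_table(config.ct)
        expr = ct_to_abundance(ct)
        candidates = list(expr.features)
        stage_counts = {"input": len(candidates), "selected": len(candidates)}
    else:
        if counts is None:
            if not config.counts:
                raise ValidationError(f"{config.mode} mode requires a count matrix")
            counts = read_matrix(config.counts)
        if lengths is None and config.lengths:
            lengths = read_lengths(config.lengths)
        if design is None:
            raise ValidationError("screening requires a design table")
        expr_full = _normalize(config, counts, lengths)
        try:
            ptable, candidates, stage_counts = screen(
                counts, expr_full, design, config.p_threshold, config.top_n
            )
        except ValidationError as err:
            raise ValidationError(f"screening stage failed: {err}") from err
        if not candidates:
            warnings.append("empty candidate set after screening; no stability computed")
            return RunReport(stage_counts, [], None, [], warnings, manifest)
        expr = expr_full.subset(features=candidates)

    try:
        cv = cv_stability(expr)
        m = m_values(expr, pseudocount=config.pseudocount)
    except ValidationError as err:
        raise ValidationError(f"stability stage failed: {err}") from err
    table = rank_candidates(cv, m)
    if "normfinder" in config.scorers:
        if design is None:
            warnings.append("normfinder requested without a design table; skipped")
        else:
            try:
                nf = normfinder_stability(expr, design, pseudocount=config.pseudocount)
                table["normfinder"] = nf.reindex(table.index)
            except ValidationError as err:
                warnings.append(f"normfinder skipped: {err}")
    mean_expr = np.log2(expr.values + 1.0).mean(axis=1)
    table.insert(0, "mean_log2_expr", mean_expr.reindex(table.index))

    combos: list[ComboStability] = []
    for k in config.combo_sizes:
        if k <= len(table):
            combos.extend(evaluate_combos(table, k, config.combo_strategy))
        else:
            warnings.append(f"combo size {k} exceeds candidate count {len(table)}; skipped")

    report = RunReport(stage_counts, list(candidates), table, combos, warnings, manifest)
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "stability.tsv", sep="\t")
        (out / "report.json").write_text(report.to_json())
        if config.mode != "qPCR":
            ptable.to_csv(out / "screen.tsv", sep="\t")
    return report
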