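"""Report assembly: the recommended diagnostic workflow end to end.

Catch suspect items starting from the item-total and item-rest
correlations, proceed to the item-total regressions, and drill down into
the distractor plots of flagged items.  ``run_pipeline`` materialises every
stage as plain CSV/JSON files under a run directory with a manifest naming
each artifact and its digest; running the same configuration twice yields
byte-identical tables.  Exit status (in the CLI) reflects errors only,
never flags.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScoredMatrix, load_responses, load_scoring_rules, score_responses
from .ctt import CTTReport, ctt_report
from .interaction import IMParams, fit_interaction
from .rasch import RaschParams, fit_rasch_cml
from .regressions import RegressionCurveSet, compare_itr, distractor_regression

__all__ = ["RunConfig", "ItemFlag", "flag_items", "run_pipeline", "PipelineError"]

log = logging.getLogger("itemlens")

ALL_STAGES = ("score", "ctt", "rasch", "im", "regressions", "distractors")


class PipelineError(RuntimeError):
    """An upstream failure with the stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one diagnostic run."""

    records: str | Path
    rules: str | Path
    out_dir: str | Path
    stages: tuple[str, ...] = ALL_STAGES
    curtain_lower: float = 0.05
    curtain_upper: float = 0.95
    rir_floor: float = 0.35
    gap_threshold: float = 0.15
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for thr in (self.rir_floor, self.gap_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError("flag thresholds must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass(frozen=True)
class ItemFlag:
    """A machine-readable reason an item needs inspection."""

    item: str
    code: str  # LOW_RIR | IM_RASCH_GAP | NONMONOTONE_EMPIRICAL
    value: float
    threshold: float


def _interior_slope(curves: RegressionCurveSet, k: int) -> float:
    """Weighted LS slope of the empirical ITR over the inter-curtain range."""
    lo, hi = curves.curtain_low, curves.curtain_high
    sel = slice(lo, hi + 1)
    s = curves.grid[sel].astype(float)
    y = curves.empirical[sel, k]
    w = curves.n_s[sel].astype(float)
    ok = np.isfinite(y) & (w > 0)
    if ok.sum() < 2:
        return np.nan
    s, y, w = s[ok], y[ok], w[ok]
    sbar = np.average(s, weights=w)
    ybar = np.average(y, weights=w)
    denom = np.average((s - sbar) ** 2, weights=w)
    if denom == 0:
        return np.nan
    return float(np.average((s - sbar) * (y - ybar), weights=w) / denom)


def flag_items(
    ctt: CTTReport,
    curves: RegressionCurveSet,
    rir_floor: float = 0.35,
    gap_threshold: float = 0.15,
) -> list[ItemFlag]:
    """Flag items with low rest-score discrimination, a large IM-Rasch gap
    inside the curtains, or a non-increasing empirical regression.

    Low discrimination always means trouble of one kind or another; an item
    whose rir is undefined (constant column) is flagged the same way.
    """
    if ctt.items != curves.items:
        raise ValueError("CTT report and curve set describe different items")
    flags: list[ItemFlag] = []
    lo, hi = curves.curtain_low, curves.curtain_high
    sel = slice(lo, hi + 1)
    for k, item in enumerate(ctt.items):
        rir = ctt.rir[k]
        if np.isnan(rir) or rir < rir_floor:
            flags.append(ItemFlag(item, "LOW_RIR", float(rir), rir_floor))
        gap = float(np.nanmax(np.abs(curves.im[sel, k] - curves.rasch[sel, k])))
        if gap > gap_threshold:
            flags.append(ItemFlag(item, "IM_RASCH_GAP", gap, gap_threshold))
        slope = _interior_slope(curves, k)
        if np.isfinite(slope) and slope < 0:
            flags.append(ItemFlag(item, "NONMONOTONE_EMPIRICAL", slope, 0.0))
    return flags


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages and write the report bundle.

    Returns a dict with the in-memory objects (matrix, ctt, rasch, im,
    curves, distractors, flags) and the manifest of written files.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    bundle: dict = {}

    def _stage(name):
        return name in config.stages

    try:
        records = load_responses(config.records)
        rules = load_scoring_rules(config.rules)
        matrix = score_responses(records, rules)
    except Exception as e:  # noqa: BLE001 - stage context is the contract
        raise PipelineError("score", e) from e
    bundle["matrix"] = matrix
    if _stage("score"):
        matrix.to_csv(out / "scored.csv")
        written["scored.csv"] = out / "scored.csv"
        written["scored.json"] = out / "scored.json"
        log.info("stage score: %d persons x %d items", matrix.n_persons, matrix.n_items)

    if _stage("ctt"):
        try:
            ctt = ctt_report(matrix)
        except Exception as e:
            raise PipelineError("ctt", e) from e
        bundle["ctt"] = ctt
        ctt.to_csv(out / "ctt_items.csv")
        ctt.to_json(out / "ctt_test.json")
        written["ctt_items.csv"] = out / "ctt_items.csv"
        written["ctt_test.json"] = out / "ctt_test.json"
        log.info("stage ctt: alpha=%.4f", ctt.alpha)

    rasch = im = None
    if _stage("rasch"):
        try:
            rasch = fit_rasch_cml(matrix)
        except Exception as e:
            raise PipelineError("rasch", e) from e
        bundle["rasch"] = rasch
        rasch.to_json(out / "rasch_params.json")
        written["rasch_params.json"] = out / "rasch_params.json"
        log.info("stage rasch: loglik=%.3f iter=%d", rasch.loglik, rasch.n_iter)

    if _stage("im"):
        try:
            im = fit_interaction(matrix)
        except Exception as e:
            raise PipelineError("im", e) from e
        bundle["im"] = im
        im.to_json(out / "im_params.json")
        written["im_params.json"] = out / "im_params.json"
        log.info("stage im: loglik=%.3f iter=%d", im.loglik, im.n_iter)

    if _stage("regressions"):
        if rasch is None or im is None:
            raise PipelineError("regressions", RuntimeError("requires the rasch and im stages"))
        try:
            curves = compare_itr(matrix, rasch, im, config.curtain_lower, config.curtain_upper)
        except Exception as e:
            raise PipelineError("regressions", e) from e
        bundle["curves"] = curves
        curves.long_frame().to_csv(out / "itr.csv", index=False, float_format="%.10g")
        written["itr.csv"] = out / "itr.csv"

        flags = flag_items(bundle["ctt"], curves, config.rir_floor, config.gap_threshold) if "ctt" in bundle else []
        bundle["flags"] = flags
        (out / "flags.json").write_text(
            json.dumps(
                [
                    {"item": f.item, "code": f.code, "value": f.value, "threshold": f.threshold}
                    for f in flags
                ],
                indent=2,
                sort_keys=True,
            )
        )
        written["flags.json"] = out / "flags.json"
        log.info("stage regressions: %d flags", len(flags))

    if _stage("distractors"):
        try:
            sets = [distractor_regression(records, rules, matrix, item) for item in matrix.items]
        except Exception as e:
            raise PipelineError("distractors", e) from e
        bundle["distractors"] = sets
        pd.concat([d.to_frame() for d in sets], ignore_index=True).to_csv(
            out / "distractors.csv", index=False, float_format="%.10g"
        )
        written["distractors.csv"] = out / "distractors.csv"
        log.info("stage distractors: %d items", len(sets))

    manifest = {name: _sha256(path) for name, path in sorted(written.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
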