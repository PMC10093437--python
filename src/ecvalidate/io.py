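"""Dataset I/O, report rendering and run-artifact serialization.

The human-readable report prints overall accuracy and average error
consistency as percentages in the compact "OA (SD)/AEC (SD)" cell style —
e.g. ``75 (0.6)/72 (2.5)`` — with integer means and one-decimal standard
deviations.  Machine outputs (JSON summary and per-repetition CSVs) keep
full precision and are deterministic for a given master seed: every
number in the report is recomputable from the emitted CSVs alone, and
wall-clock timing appears only in the human-readable report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset
from .engine import RunResult
from .exceptions import InvalidInputError


def _round_trip_float(value: float) -> float | None:
    """JSON-safe float: NaN becomes None (JSON null)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_dataset(path, label_column: str, id_column: str | None = None) -> Dataset:
    """Read a CSV with a header row into a :class:`Dataset`.

    All non-label (and non-id) columns are features and must be numeric;
    ids are taken verbatim from ``id_column`` when given, otherwise
    assigned 0..N−1 in row order.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"dataset file not found: {path}")
    frame = pd.read_csv(path)
    return Dataset.from_dataframe(frame, label_column, id_column)


def write_dataset(ds: Dataset, path, label_column: str = "label",
                  id_column: str = "sample_id") -> None:
    ds.to_dataframe(label_column, id_column).to_csv(path, index=False)


def format_percent_cell(mean: float, sd: float) -> str:
    """One Table-style cell: percentage mean (integer) with SD (1 decimal).

    0.75 ± 0.006 renders as ``75 (0.6)``; an undefined mean renders ``NA``.
    """
    if mean is None or math.isnan(mean):
        return "NA"
    if sd is None or math.isnan(sd):
        return f"{round(mean * 100)} (NA)"
    return f"{round(mean * 100)} ({sd * 100:.1f})"


def format_oa_aec_cell(mean_oa: float, sd_oa: float,
                       aec: float, aec_sd: float) -> str:
    """The combined ``OA (SD)/AEC (SD)`` cell, percentages throughout."""
    return f"{format_percent_cell(mean_oa, sd_oa)}/{format_percent_cell(aec, aec_sd)}"


@dataclass
class RunReport:
    """Human-facing summary of one validation run."""

    classifier: str
    approach: str
    n_samples: int
    n_error_sets: int
    config: dict
    cell: str
    mean_oa: float
    sd_oa: float
    aec: float
    aec_sd: float
    n_pairs_defined: int
    n_pairs_undefined: int
    mean_val_accuracy: float | None = None
    artifacts: list[str] = field(default_factory=list)
    wall_clock_s: float | None = None

    def text(self) -> str:
        lines = [
            "EC-enhanced K-Fold validation",
            "=" * 45,
            f"classifier        : {self.classifier}",
            f"approach          : {self.approach}  "
            f"(K={self.config.get('k')}, m={self.config.get('m')}, "
            f"seed={self.config.get('master_seed')})",
            f"samples           : {self.n_samples}",
            f"error sets (n)    : {self.n_error_sets}",
            f"OA (SD) / AEC (SD): {self.cell}   [percent]",
            f"pairs defined     : {self.n_pairs_defined}"
            f"   undefined: {self.n_pairs_undefined}",
        ]
        if self.aec is None or (isinstance(self.aec, float) and math.isnan(self.aec)):
            lines.append("note: AEC is NA — every model pair was perfect "
                         "(no errors to be consistent on)")
        if self.mean_val_accuracy is not None:
            lines.append(f"mean validation accuracy: "
                         f"{self.mean_val_accuracy * 100:.1f}%")
        if self.wall_clock_s is not None:
            lines.append(f"wall clock        : {self.wall_clock_s:.1f} s")
        if self.artifacts:
            lines.append("artifacts         : " + ", ".join(self.artifacts))
        return "\n".join(lines)


def render_report(result: RunResult, artifacts: list[str] | None = None,
                  wall_clock_s: float | None = None) -> RunReport:
    """Render a :class:`RunResult` in the percentage cell style."""
    s = result.ec_summary
    mean_val = (float(np.mean(result.val_accuracy_per_model))
                if result.val_accuracy_per_model is not None else None)
    return RunReport(
        classifier=result.classifier,
        approach=result.config.approach,
        n_samples=result.n_samples,
        n_error_sets=result.n_error_sets,
        config=result.config.to_dict(),
        cell=format_oa_aec_cell(result.mean_oa, result.sd_oa, s.aec, s.sd),
        mean_oa=result.mean_oa, sd_oa=result.sd_oa,
        aec=s.aec, aec_sd=s.sd,
        n_pairs_defined=s.n_pairs_defined,
        n_pairs_undefined=s.n_pairs_undefined,
        mean_val_accuracy=mean_val,
        artifacts=list(artifacts or []),
        wall_clock_s=wall_clock_s,
    )


def write_run_artifacts(result: RunResult, out_dir,
                        wall_clock_s: float | None = None,
                        write_pairwise: bool | None = None) -> dict[str, Path]:
    """Write the machine outputs of a run into ``out_dir``.

    Emits ``summary.json`` (config echo, seeds, metrics), ``oa.csv``
    (per-repetition OA), ``error_sets.csv`` (long-format membership) and,
    when the pairwise matrix is materialisable within the configured cap,
    ``pairwise_ec.csv`` with undefined values as empty fields.  Machine
    outputs are byte-identical across runs with the same master seed;
    ``report.txt`` (human-readable) additionally carries wall-clock time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summary"] = out_dir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    paths["oa"] = out_dir / "oa.csv"
    result.oa_frame().to_csv(paths["oa"], index=False)

    paths["error_sets"] = out_dir / "error_sets.csv"
    result.error_sets_frame().to_csv(paths["error_sets"], index=False)

    if write_pairwise is None:
        write_pairwise = result.n_error_sets <= result.config.pairwise_cap
    if write_pairwise:
        paths["pairwise"] = out_dir / "pairwise_ec.csv"
        result.pairwise().to_csv(paths["pairwise"])

    report = render_report(result,
                           artifacts=[p.name for p in paths.values()],
                           wall_clock_s=wall_clock_s)
    paths["report"] = out_dir / "report.txt"
    with open(paths["report"], "w") as fh:
        fh.write(report.text() + "\n")
    return paths
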