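"""Three cohort comparison designs over co-registered contour sets.

The designs mirror how contour variability is studied in radiotherapy:

* **interobserver** — two human observers compared on the same sequence
  (one comparison per sequence per structure per patient);
* **intersequence** — one observer compared with themselves across
  sequence pairs (T1WI-T1dixonc, T1WI-T2WI, T2WI-T1dixonc);
* **auto_vs_manual** — the automatic observer compared against each human
  observer per sequence, plus the automatic observer's own intersequence
  agreement.

The automatic observer is just another observer label, so all designs run
through one comparison engine.  Per patient, structure and pair the engine
records DSC, undirected HD, 95% HD and both volumes; summaries are then
mean ± SD *across patients* (no pooling of voxels across patients), with a
volume ICC(2,1) and a Wilcoxon rank-sum p per (structure, comparison)
cell.  Missing or empty structures are recorded as "not available" and
excluded from aggregation with per-cell n reported — never zero-imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core import (
    CohortIndex,
    GridMismatchError,
    LabelVolume,
    StructureLabel,
    load_label_volume,
)
from .metrics import MetricUndefinedError, pair_metrics
from .stats import icc_2_1, summarize_mean_sd, wilcoxon_rank_sum, wilcoxon_signed_rank

__all__ = [
    "ComparisonSpec",
    "MetricRecord",
    "DesignResult",
    "run_interobserver",
    "run_intersequence",
    "run_auto_vs_manual",
    "run_designs",
    "write_report",
]

logger = logging.getLogger("contourvar")

DESIGNS = ("interobserver", "intersequence", "auto_vs_manual")
METRIC_NAMES = ("dsc", "hd95", "hd", "volume_a", "volume_b")


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison: what varies, what is held fixed.

    ``varied_axis`` is ``"observer"`` or ``"sequence"``; ``pair`` holds the
    two labels on that axis and ``fixed`` the label on the other axis.
    """

    design: str
    varied_axis: str
    pair: tuple[str, str]
    fixed: str

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.varied_axis not in ("observer", "sequence"):
            raise ValueError(f"varied_axis must be observer|sequence")
        if self.pair[0] == self.pair[1]:
            raise ValueError("comparison pair must differ")
        if self.design == "interobserver" and self.varied_axis != "observer":
            raise ValueError("interobserver pairs differ only in observer")
        if self.design == "intersequence" and self.varied_axis != "sequence":
            raise ValueError("intersequence pairs differ only in sequence")
        if (
            self.design == "auto_vs_manual"
            and self.varied_axis == "observer"
            and "AUTO" not in self.pair
        ):
            raise ValueError("auto_vs_manual must pair a human observer with AUTO")

    def cell(self, member: int) -> tuple[str, str]:
        """(observer, sequence) for one side of the comparison."""
        if self.varied_axis == "observer":
            return self.pair[member], self.fixed
        return self.fixed, self.pair[member]

    @property
    def label(self) -> str:
        """Human-readable comparison label used in tables."""
        if self.varied_axis == "observer":
            return f"{self.pair[0]}-{self.pair[1]}@{self.fixed}"
        return f"{self.fixed}:{self.pair[0]}-{self.pair[1]}"


@dataclass(frozen=True)
class MetricRecord:
    """One metric value with full provenance; ``value`` None = not available."""

    patient_id: str
    structure: str
    design: str
    comparison: str
    observer_a: str
    sequence_a: str
    observer_b: str
    sequence_b: str
    metric: str
    value: float | None
    note: str = ""


@dataclass
class DesignResult:
    """Records plus the per-design aggregation tables."""

    design: str
    records: pd.DataFrame
    summary: pd.DataFrame       # metric x structure x comparison: n, mean, sd
    volume_stats: pd.DataFrame  # structure x comparison: ICC(2,1), Wilcoxon p


def _na_records(spec: ComparisonSpec, patient: str, structure: StructureLabel, note: str):
    (oa, sa), (ob, sb) = spec.cell(0), spec.cell(1)
    return [
        MetricRecord(
            patient, structure.value, spec.design, spec.label,
            oa, sa, ob, sb, metric, None, note,
        )
        for metric in METRIC_NAMES
    ]


def evaluate_comparison(
    cohort: CohortIndex,
    spec: ComparisonSpec,
    percentile: float = 95.0,
    points: str = "boundary",
    _cache: dict | None = None,
) -> list[MetricRecord]:
    """All per-patient, per-structure records for one comparison."""
    records: list[MetricRecord] = []
    (oa, sa), (ob, sb) = spec.cell(0), spec.cell(1)
    load = _cached_loader(_cache)
    for patient in cohort.patients:
        if cohort.get(patient, oa, sa, list(StructureLabel)[0]) is None and all(
            cohort.get(patient, oa, sa, s) is None for s in StructureLabel
        ):
            continue  # patient absent from this cell entirely
        for structure in StructureLabel:
            pa = cohort.get(patient, oa, sa, structure)
            pb = cohort.get(patient, ob, sb, structure)
            if pa is None or pb is None:
                side = f"{oa}/{sa}" if pa is None else f"{ob}/{sb}"
                logger.warning(
                    "%s %s: %s missing for %s — recorded as not available",
                    patient, spec.label, structure.value, side,
                )
                records.extend(_na_records(spec, patient, structure, "missing mask"))
                continue
            try:
                pm = pair_metrics(load(pa), load(pb), percentile, points)
            except (MetricUndefinedError, GridMismatchError) as exc:
                logger.warning(
                    "%s %s %s: %s — recorded as not available",
                    patient, spec.label, structure.value, exc,
                )
                records.extend(_na_records(spec, patient, structure, str(exc)))
                continue
            for metric in METRIC_NAMES:
                records.append(
                    MetricRecord(
                        patient, structure.value, spec.design, spec.label,
                        oa, sa, ob, sb, metric, float(getattr(pm, metric)),
                    )
                )
        logger.debug("%s: %s done", spec.label, patient)
    return records


def _cached_loader(cache: dict | None):
    if cache is None:
        return load_label_volume

    def load(path: Path) -> LabelVolume:
        key = str(path)
        if key not in cache:
            cache[key] = load_label_volume(path)
        return cache[key]

    return load


def _records_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if not df.empty:
        df = df.sort_values(
            ["design", "comparison", "structure", "patient_id", "metric"]
        ).reset_index(drop=True)
    return df


def _aggregate(design: str, records: Sequence[MetricRecord], volume_test: str) -> DesignResult:
    df = _records_frame(records)
    if df.empty:
        raise ValueError(f"{design}: no records produced — is the cohort empty?")
    agreement = df[df["metric"].isin(("dsc", "hd95"))]
    summary = summarize_mean_sd(agreement, ["metric", "structure", "comparison"])

    vol_rows = []
    wide = df[df["metric"].isin(("volume_a", "volume_b"))].pivot_table(
        index=["structure", "comparison", "patient_id"],
        columns="metric", values="value", dropna=False,
    )
    for (structure, comparison), cell in wide.groupby(level=[0, 1], observed=True):
        pairs = cell.dropna()
        row: dict = {
            "design": design, "structure": structure, "comparison": comparison,
            "n": len(pairs), "icc": np.nan, "icc_good": False,
            "p_value": np.nan, "significant": False,
            "mean_volume_a": np.nan, "mean_volume_b": np.nan,
        }
        if len(pairs) >= 2:
            mat = pairs[["volume_a", "volume_b"]].to_numpy()
            icc = icc_2_1(mat)
            if volume_test == "signed_rank":
                test = wilcoxon_signed_rank(mat[:, 0], mat[:, 1])
            else:
                test = wilcoxon_rank_sum(mat[:, 0], mat[:, 1])
            row.update(
                icc=icc.icc, icc_good=icc.good,
                p_value=test.p_value, significant=test.significant,
                mean_volume_a=float(mat[:, 0].mean()),
                mean_volume_b=float(mat[:, 1].mean()),
            )
        vol_rows.append(row)
    volume_stats = pd.DataFrame(vol_rows).sort_values(["structure", "comparison"]).reset_index(drop=True)
    return DesignResult(design, df, summary, volume_stats)


def _sequence_pairs(sequences: Sequence[str]) -> list[tuple[str, str]]:
    ordered = [s for s in ("T1WI", "T1dixonc", "T2WI") if s in sequences]
    ordered += [s for s in sequences if s not in ordered]
    # canonical pair order as reported: T1WI-T1dixonc, T1WI-T2WI, T2WI-T1dixonc
    pairs = []
    if {"T1WI", "T1dixonc"} <= set(ordered):
        pairs.append(("T1WI", "T1dixonc"))
    if {"T1WI", "T2WI"} <= set(ordered):
        pairs.append(("T1WI", "T2WI"))
    if {"T2WI", "T1dixonc"} <= set(ordered):
        pairs.append(("T2WI", "T1dixonc"))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if (a, b) not in pairs and (b, a) not in pairs:
                pairs.append((a, b))
    return pairs


def _observer_sequences(cohort: CohortIndex, *observers: str) -> list[str]:
    """Sequences (ground truth excluded) on which all given observers appear."""
    per_obs = [
        {e.sequence for e in cohort.entries if e.observer == obs} for obs in observers
    ]
    present = set.intersection(*per_obs) if per_obs else set()
    return [s for s in sorted(present) if s != "GT"]


def run_interobserver(
    cohort: CohortIndex,
    observers: tuple[str, str] = ("R1", "R2"),
    percentile: float = 95.0,
    points: str = "boundary",
    volume_test: str = "rank_sum",
) -> DesignResult:
    """Compare two observers on every sequence both have contoured."""
    cache: dict = {}
    records: list[MetricRecord] = []
    for seq in _observer_sequences(cohort, *observers):
        spec = ComparisonSpec("interobserver", "observer", observers, seq)
        records.extend(evaluate_comparison(cohort, spec, percentile, points, cache))
    return _aggregate("interobserver", records, volume_test)


def run_intersequence(
    cohort: CohortIndex,
    observer: str = "R2",
    percentile: float = 95.0,
    points: str = "boundary",
    volume_test: str = "rank_sum",
) -> DesignResult:
    """Compare one observer's contours across all sequence pairs."""
    sequences = _observer_sequences(cohort, observer)
    if len(sequences) < 2:
        raise ValueError("intersequence design needs the observer on >= 2 sequences")
    cache: dict = {}
    records: list[MetricRecord] = []
    for pair in _sequence_pairs(sequences):
        spec = ComparisonSpec("intersequence", "sequence", pair, observer)
        records.extend(evaluate_comparison(cohort, spec, percentile, points, cache))
    return _aggregate("intersequence", records, volume_test)


def run_auto_vs_manual(
    cohort: CohortIndex,
    human_observers: tuple[str, ...] = ("R1", "R2"),
    percentile: float = 95.0,
    points: str = "boundary",
    volume_test: str = "rank_sum",
) -> DesignResult:
    """AUTO vs each human observer per sequence, plus AUTO across sequences."""
    if "AUTO" not in cohort.observers:
        raise ValueError("auto_vs_manual design needs an AUTO observer")
    cache: dict = {}
    records: list[MetricRecord] = []
    auto_sequences = _observer_sequences(cohort, "AUTO")
    skipped = set(cohort.sequences) - set(auto_sequences) - {"GT"}
    if skipped:
        logger.warning("AUTO missing on %s — those sequences skipped", sorted(skipped))
    for seq in auto_sequences:
        for human in human_observers:
            if human not in cohort.observers:
                logger.warning("observer %s absent — skipped in auto_vs_manual", human)
                continue
            spec = ComparisonSpec("auto_vs_manual", "observer", (human, "AUTO"), seq)
            records.extend(evaluate_comparison(cohort, spec, percentile, points, cache))
    if len(auto_sequences) >= 2:
        for pair in _sequence_pairs(auto_sequences):
            spec = ComparisonSpec("auto_vs_manual", "sequence", pair, "AUTO")
            records.extend(evaluate_comparison(cohort, spec, percentile, points, cache))
    else:
        logger.warning("AUTO present on < 2 sequences — AUTO intersequence skipped")
    return _aggregate("auto_vs_manual", records, volume_test)


def run_designs(
    cohort: CohortIndex,
    designs: Sequence[str] = DESIGNS,
    observer: str = "R2",
    percentile: float = 95.0,
    points: str = "boundary",
    volume_test: str = "rank_sum",
) -> dict[str, DesignResult]:
    """Run the requested designs with shared settings."""
    results: dict[str, DesignResult] = {}
    kwargs = dict(percentile=percentile, points=points, volume_test=volume_test)
    for design in designs:
        logger.info("running design %s", design)
        if design == "interobserver":
            results[design] = run_interobserver(cohort, **kwargs)
        elif design == "intersequence":
            results[design] = run_intersequence(cohort, observer=observer, **kwargs)
        elif design == "auto_vs_manual":
            results[design] = run_auto_vs_manual(cohort, **kwargs)
        else:
            raise ValueError(f"unknown design {design!r}")
    return results


def _file_md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(
    results: Mapping[str, DesignResult],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    cohort: CohortIndex | None = None,
) -> dict[str, Path]:
    """Write per-design summary/volume CSVs, the long records CSV and a
    reproducibility manifest (config, seed, package version, input checksums).

    Re-running with the same inputs and seed reproduces every file
    byte-for-byte (no timestamps are recorded).
    """
    if not results:
        raise ValueError("nothing to report: no design results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    all_records = pd.concat([r.records for r in results.values()], ignore_index=True)
    rec_path = out_dir / "records.csv"
    all_records.to_csv(rec_path, index=False, float_format="%.9g")
    paths["records"] = rec_path

    for name, res in results.items():
        sp = out_dir / f"{name}_summary.csv"
        res.summary.to_csv(sp, index=False, float_format="%.9g")
        paths[f"{name}_summary"] = sp
        vp = out_dir / f"{name}_volume_stats.csv"
        res.volume_stats.to_csv(vp, index=False, float_format="%.9g")
        paths[f"{name}_volume_stats"] = vp

    checksums = {}
    if cohort is not None:
        manifest_csv = cohort.root / "manifest.csv"
        if manifest_csv.exists():
            checksums["manifest.csv"] = _file_md5(manifest_csv)
        for e in sorted(cohort.entries, key=lambda e: str(e.path))[:: max(1, len(cohort.entries) // 200)]:
            try:
                checksums[str(e.path.relative_to(cohort.root))] = _file_md5(e.path)
            except (ValueError, FileNotFoundError):
                continue
    manifest = {
        "package": "contourvar",
        "version": _pkg_version,
        "seed": seed,
        "config": dict(config or {}),
        "designs": sorted(results),
        "n_records": int(len(all_records)),
        "input_checksums": checksums,
    }
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = man_path
    return paths
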