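"""End-to-end pipeline: simulate/ingest → QC → band analytic → wPLI → NBS → report.

Driven by a structured YAML/dict config; every stage logs to a line-oriented
log with ISO timestamps and any stage failure aborts with the stage name and
subject id.  Outputs are machine-readable delimited text plus BrainNet
Viewer export files for significant components.
"""

from __future__ import annotations

import datetime
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasInfo, load_aal90, load_atlas
from .bands import get_band
from .connectivity import read_connectivity, subject_connectivity, write_connectivity
from .nbs import DesignSpec, NBSResults, NetworkBasedStatistic, zscore_edges
from .preprocess import band_analytic, enforce_minimum, exclude_epochs
from .report import export_brainnet, identify_hubs, node_degree
from .simulate import SyntheticCohortSpec, generate_cohort

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str | None, message: str):
        self.stage = stage
        self.subject_id = subject_id
        super().__init__(
            f"stage {stage!r}"
            + (f", subject {subject_id!r}" if subject_id else "")
            + f": {message}"
        )


@dataclass
class PipelineResult:
    """Bundle of everything the pipeline produced."""

    cohort: pd.DataFrame
    results: dict[tuple[str, str], NBSResults]  # (band, design label) -> results
    summary: pd.DataFrame
    qc_counts: pd.DataFrame
    out_dir: Path | None = None
    log_lines: list[str] = field(default_factory=list)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh)


def _validate_config(cfg: dict) -> None:
    if cfg.get("source") not in ("simulate", "matrices"):
        raise PipelineError("config", None, "source must be 'simulate' or 'matrices'")
    rate = float(cfg.get("cohort", {}).get("sampling_rate", 300.0))
    for name in cfg.get("bands", []):
        band = get_band(name)
        if cfg["source"] == "simulate" and band.high >= rate / 2:
            raise PipelineError(
                "config",
                None,
                f"band {name!r} upper edge {band.high} Hz is not below Nyquist "
                f"at {rate} Hz sampling",
            )


def run_pipeline(config, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the configured pipeline and (optionally) write a result bundle."""
    cfg = load_config(config)
    _validate_config(cfg)
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(f"{datetime.datetime.now().isoformat(timespec='seconds')} {msg}")

    seed = int(cfg.get("seed", 0))
    say(f"pipeline start seed={seed} megconn={__version__} python={platform.python_version()}")

    band_names = cfg.get("bands", ["alpha"])
    qc_cfg = cfg.get("qc", {})
    motion_limit = float(qc_cfg.get("motion_limit", 5.0))
    amplitude_limit = qc_cfg.get("amplitude_limit", None)
    if amplitude_limit is not None:
        amplitude_limit = float(amplitude_limit)
    min_epochs = int(qc_cfg.get("min_epochs", 6))

    # ---- stage: ingest ----------------------------------------------------
    if cfg["source"] == "simulate":
        spec = SyntheticCohortSpec(**{**cfg.get("cohort", {}), "seed": seed})
        try:
            cohort = generate_cohort(spec)
        except Exception as e:  # pragma: no cover - simulator errors are rare
            raise PipelineError("simulate", None, str(e)) from e
        table = cohort.table
        series_by_subject = dict(zip(table["subject_id"], cohort.series))
        say(f"simulated cohort: {len(table)} subjects, {spec.n_regions} regions")
        matrices_by_band = None
    else:
        table = pd.read_csv(cfg["cohort_table"])
        series_by_subject = None
        matrices_by_band = {
            b: [read_connectivity(p) for p in sorted(Path(cfg["matrix_dir"]).glob(f"*_{b}.csv"))]
            for b in band_names
        }
        first = matrices_by_band[band_names[0]]
        if not first:
            raise PipelineError("ingest", None, f"no *_{band_names[0]}.csv matrices found")
        order = [m.subject_id for m in first]
        missing = set(order) - set(table["subject_id"])
        if missing:
            raise PipelineError(
                "ingest", sorted(missing)[0], "connectivity matrix without cohort row"
            )
        # align cohort rows with the matrix stack order
        table = (
            table.set_index("subject_id").loc[order].reset_index()
        )
        say(f"loaded cohort table: {len(table)} subjects")

    # ---- stage: QC + connectivity -----------------------------------------
    qc_rows = []
    if series_by_subject is not None:
        matrices_by_band = {b: [] for b in band_names}
        included = []
        for sid, series in series_by_subject.items():
            try:
                clean = exclude_epochs(
                    series, motion_limit=motion_limit, amplitude_limit=amplitude_limit
                )
                ok = enforce_minimum(clean, minimum=min_epochs)
                qc_rows.append(
                    {
                        "subject_id": sid,
                        "epochs_in": series.n_epochs,
                        "epochs_kept": clean.n_epochs,
                        "included": ok,
                    }
                )
                if not ok:
                    say(f"QC exclude subject {sid}: {clean.n_epochs} epochs < {min_epochs}")
                    continue
                included.append(sid)
                for bname in band_names:
                    analytic = band_analytic(clean, get_band(bname))
                    matrices_by_band[bname].append(subject_connectivity(analytic))
            except Exception as e:
                raise PipelineError("connectivity", sid, str(e)) from e
        table = table[table["subject_id"].isin(included)].reset_index(drop=True)
        say(f"QC complete: {len(included)} subjects included")
    qc_counts = pd.DataFrame(qc_rows)

    # ---- stage: NBS per design per band -----------------------------------
    results: dict[tuple[str, str], NBSResults] = {}
    summary_rows = []
    for d_cfg in cfg.get("designs", []):
        d_cfg = dict(d_cfg)
        label = d_cfg.pop("label", d_cfg.get("predictor", "design"))
        nperm = int(d_cfg.pop("n_permutations", 5000))
        design = DesignSpec(n_permutations=nperm, seed=seed, **d_cfg)
        for bname in band_names:
            mats = matrices_by_band[bname]
            try:
                model = NetworkBasedStatistic.from_matrices(mats, table, design)
                res = model.fit()
            except Exception as e:
                raise PipelineError(f"nbs[{bname}:{label}]", None, str(e)) from e
            results[(bname, label)] = res
            say(
                f"NBS {bname}/{label}: threshold={res.threshold:.3f}, "
                f"{len(res.components)} components, "
                f"{len(res.significant_components())} significant"
            )
            for k, comp in enumerate(res.components):
                summary_rows.append(
                    {
                        "band": bname,
                        "design": label,
                        "component": k,
                        "extent": comp.extent,
                        "n_nodes": len(comp.nodes),
                        "p_corrected": comp.p_corrected,
                        "significant": comp.p_corrected <= design.alpha,
                    }
                )
    summary = pd.DataFrame(
        summary_rows,
        columns=["band", "design", "component", "extent", "n_nodes", "p_corrected", "significant"],
    )

    # ---- stage: report / export -------------------------------------------
    result = PipelineResult(
        cohort=table, results=results, summary=summary, qc_counts=qc_counts, log_lines=log
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.out_dir = out_dir
        table.to_csv(out_dir / "cohort.csv", index=False)
        summary.to_csv(out_dir / "nbs_summary.csv", index=False)
        if len(qc_counts):
            qc_counts.to_csv(out_dir / "qc_counts.csv", index=False)
        conn_dir = out_dir / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for bname, mats in matrices_by_band.items():
            for m in mats:
                write_connectivity(m, conn_dir / f"{m.subject_id}_{bname}.csv")
        atlas = _resolve_atlas(cfg, next(iter(matrices_by_band.values()))[0].n_regions)
        for (bname, label), res in results.items():
            for k, comp in enumerate(res.significant_components()):
                if atlas is not None:
                    export_brainnet(
                        comp,
                        atlas,
                        out_dir / f"network_{bname}_{label}_{k}.node",
                        out_dir / f"network_{bname}_{label}_{k}.edge",
                    )
                hubs = identify_hubs(node_degree(comp), top_k=10, atlas=atlas)
                pd.DataFrame(hubs, columns=["label", "region", "degree"]).to_csv(
                    out_dir / f"hubs_{bname}_{label}_{k}.csv", index=False
                )
        meta = {
            "seed": seed,
            "megconn_version": __version__,
            "numpy_version": np.__version__,
            "n_subjects": int(len(table)),
            "bands": band_names,
        }
        (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
        say(f"outputs written to {out_dir}")
    return result


def _resolve_atlas(cfg: dict, n_regions: int) -> AtlasInfo | None:
    if "atlas" in cfg:
        return load_atlas(cfg["atlas"])
    if n_regions == 90:
        return load_aal90()
    return None
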