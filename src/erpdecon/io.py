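"""Recording containers, on-disk formats, and the end-to-end pipeline.

Primary interchange formats are deliberately plain: continuous data as
delimited text or raw float64 with a JSON header, events as BIDS-style
TSV, results as long-format CSV, configs as JSON.  An optional adapter
for FIF containers (via :mod:`mne`) lives behind ``format="fif"`` and
degrades gracefully when mne is not installed.

The pipeline (:func:`run_pipeline`) wires config → design → time
expansion → artifact blanking → solver → rERP conversion → export,
logging every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import artifacts as _artifacts
from . import design as _design
from . import results as _results
from . import solve as _solve
from . import timeexpand as _tx
from .formula import ModelSpec, validate_spec

__all__ = [
    "Recording",
    "load_recording",
    "save_recording",
    "load_config",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger("erpdecon")


@dataclass
class Recording:
    """Continuous multichannel data with sampling metadata."""

    data: np.ndarray  # channels × samples
    srate: float
    channels: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.srate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate


def _header_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_recording(rec: Recording, path, format: str = "binary") -> Path:
    """Write a recording plus JSON sidecar header; returns the data path."""
    path = Path(path)
    header = {
        "srate": rec.srate,
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "channels": rec.channels,
        "format": format,
    }
    if format == "binary":
        rec.data.astype("<f8").tofile(path)
        header["dtype"] = "<f8"
    elif format == "delimited":
        np.savetxt(path, rec.data, delimiter="\t", fmt="%.12g")
    else:
        raise ValueError(f"unknown format {format!r}")
    _header_path(path).write_text(json.dumps(header, indent=1))
    return path


def load_recording(path, format: Optional[str] = None) -> Recording:
    """Load a recording (``binary``, ``delimited``, or ``fif``).

    For the plain formats, a ``<path>.json`` sidecar must provide at
    least ``srate``; ``binary`` additionally needs ``n_channels``.
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".fif":
            format = "fif"
        else:
            hdr = _header_path(path)
            format = (
                json.loads(hdr.read_text()).get("format", "binary")
                if hdr.exists()
                else "delimited"
            )
    if format == "fif":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional adapter
            raise ImportError(
                "reading FIF containers requires the optional 'mne' package"
            ) from exc
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        return Recording(
            raw.get_data(),
            float(raw.info["sfreq"]),
            list(raw.ch_names),
            {"source": str(path), "format": "fif"},
        )
    hdr_path = _header_path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing header sidecar {hdr_path}")
    header = json.loads(hdr_path.read_text())
    if "srate" not in header:
        raise ValueError(f"header {hdr_path} is missing the 'srate' field")
    srate = float(header["srate"])
    if format == "binary":
        if "n_channels" not in header:
            raise ValueError(f"header {hdr_path} is missing 'n_channels'")
        data = np.fromfile(path, dtype=header.get("dtype", "<f8"))
        data = data.reshape(int(header["n_channels"]), -1)
    elif format == "delimited":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Recording(
        data,
        srate,
        list(header.get("channels", [])),
        {"source": str(path), "format": format},
    )


# ---------------------------------------------------------------------------
# configuration & pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def load_config(path) -> dict:
    """Read the JSON model/pipeline configuration."""
    with open(path) as fh:
        return json.load(fh)


def _model_spec(entry: dict) -> ModelSpec:
    basis_cfg = entry.get("basis", {"kind": "stick"})
    basis = _tx.TemporalBasis(
        kind=basis_cfg.get("kind", "stick"),
        n_basis=basis_cfg.get("n_basis"),
        n_harmonics=basis_cfg.get("n_harmonics"),
    )
    return ModelSpec(
        formula=entry["formula"],
        window=tuple(entry["window"]),
        basis=basis,
        reference_levels=entry.get("reference_levels", {}),
        coding=entry.get("coding", "treatment"),
    )


def expand_models(
    recording: Recording, events: pd.DataFrame, models: dict[str, ModelSpec]
) -> _tx.ExpandedDesign:
    """Build and assemble the expanded design for a set of models."""
    blocks = []
    for etype, spec in models.items():
        sub = events[events["type"] == etype]
        if sub.empty:
            raise ValueError(f"no events of type {etype!r}")
        diags = validate_spec(spec, sub)
        if diags:
            raise ValueError(f"model for {etype!r} invalid: " + "; ".join(diags))
        dm = _design.build_design(sub, spec)
        window = _tx.local_window(*spec.window, recording.srate)
        onsets, keep = _tx.onsets_to_samples(
            sub["onset"], recording.srate, recording.n_samples
        )
        blocks.append(
            _tx.time_expand(
                _design.DesignMatrix(
                    dm.values[keep],
                    dm.columns,
                    dm.spline_bases,
                    dm.levels,
                    dm.reference,
                )
                if not keep.all()
                else dm,
                onsets,
                window,
                spec.basis,
                recording.n_samples,
                event_type=etype,
                srate=recording.srate,
            )
        )
    return _tx.assemble(blocks, recording.srate)


def run_pipeline(config_path) -> dict:
    """Run the full analysis described by a JSON config; returns paths.

    Stages: load → design → time expansion → (optional) artifact
    blanking → solver → rERP conversion → export.  Any stage error is
    re-raised as :class:`PipelineError` tagged with the stage name.
    """
    config = load_config(config_path)
    base = Path(config_path).parent
    out_dir = Path(config.get("output_dir", "."))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    outputs = {"log": str(log_path)}
    try:
        try:
            rec_cfg = config["recording"]
            recording = load_recording(
                _resolve(rec_cfg["path"]), rec_cfg.get("format")
            )
            events = _design.load_events(
                _resolve(config["events"]), duration=recording.duration
            )
            logger.info(
                "loaded %d channels x %d samples at %g Hz; %d events",
                recording.data.shape[0],
                recording.n_samples,
                recording.srate,
                len(events),
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("load", exc) from exc

        try:
            imp = config.get("imputation")
            if imp:
                events = _design.impute_missing(
                    events, imp.get("method", "mean"), imp.get("seed")
                )
            models = {
                etype: _model_spec(entry)
                for etype, entry in config["models"].items()
            }
            expanded = expand_models(recording, events, models)
            logger.info(
                "expanded design: %d x %d, %d nonzeros",
                expanded.n_samples,
                expanded.n_columns,
                expanded.X.nnz,
            )
            if config.get("dump_design"):
                expanded.save(out_dir / "design.mtx", out_dir / "design_colmap.json")
                outputs["design"] = str(out_dir / "design.mtx")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("design", exc) from exc

        n_blanked = 0
        try:
            art = config.get("artifacts")
            if art:
                intervals = _artifacts.detect_peak2peak(
                    recording.data,
                    threshold=art["threshold"],
                    winlen=art.get("winlen", 2.0),
                    srate=recording.srate,
                    step=art.get("step"),
                )
                expanded, n_blanked = _artifacts.blank_rows(expanded, intervals)
                logger.info(
                    "artifact detection flagged %d interval(s), blanked %d rows",
                    len(intervals),
                    n_blanked,
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("artifacts", exc) from exc

        try:
            solver = config.get("solver", {})
            name = solver.get("name", "lsmr")
            if name == "lsmr":
                fit = _solve.fit_lsmr(
                    expanded,
                    recording.data,
                    tol=solver.get("tol", _solve.DEFAULT_TOL),
                    max_iter=solver.get("max_iter"),
                )
            elif name == "elasticnet":
                fit = _solve.fit_elasticnet(
                    expanded,
                    recording.data,
                    alpha=solver.get("alpha", 0.0),
                    n_lambdas=solver.get("n_lambdas", 20),
                    cv_folds=solver.get("cv_folds", 5),
                    seed=solver.get("seed", config.get("seed")),
                )
            else:
                raise ValueError(f"unknown solver {name!r}")
            logger.info("solved %d channels (%s)", fit.n_channels, name)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("solve", exc) from exc

        try:
            erps = _results.unfold_betas(fit, channels=recording.channels)
            if config.get("baseline"):
                erps = _results.baseline_correct(erps, tuple(config["baseline"]))
            csv_path = out_dir / "rerps.csv"
            _results.export_long(erps, csv_path)
            outputs["rerps"] = str(csv_path)
            meta = {
                "solver": fit.metadata,
                "sigma": fit.sigma.tolist(),
                "seed": config.get("seed"),
                "blanked_rows": n_blanked,
                "n_events": int(len(events)),
                "n_columns": int(expanded.n_columns),
            }
            meta_path = out_dir / "fit.json"
            meta_path.write_text(json.dumps(meta, indent=1))
            outputs["metadata"] = str(meta_path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("results", exc) from exc

        if config.get("mass_univariate"):
            try:
                for etype, spec in models.items():
                    sub = events[events["type"] == etype]
                    window = _tx.local_window(*spec.window, recording.srate)
                    onsets = _tx.onsets_to_samples(sub["onset"], recording.srate)
                    epochs, keep = _solve.cut_epochs(recording.data, onsets, window)
                    dm = _design.build_design(sub[keep], spec)
                    mu_fit = _solve.fit_mass_univariate(
                        dm, epochs, srate=recording.srate,
                        window=window, event_type=etype,
                    )
                    mu_erps = _results.unfold_betas(
                        mu_fit, channels=recording.channels
                    )
                    if config.get("baseline"):
                        mu_erps = _results.baseline_correct(
                            mu_erps, tuple(config["baseline"])
                        )
                    mu_path = out_dir / f"massuni_{etype}.csv"
                    _results.export_long(mu_erps, mu_path)
                    outputs[f"massuni_{etype}"] = str(mu_path)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("mass_univariate", exc) from exc

        logger.info("pipeline finished; outputs: %s", sorted(outputs))
        return outputs
    finally:
        logger.removeHandler(handler)
        handler.close()
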