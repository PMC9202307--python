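"""Run archives: self-describing HDF5 containers plus flat CSV summaries.

One group per SMC step (lambda reached, overlap metrics, decorrelation,
ln mean weight, distinct-ancestor count) and a ``final`` group with the
lambda=1 coordinates (N x D table), ancestors and energies.  The CSV
summary mirrors :meth:`RunRecord.summary_frame`.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .ensemble import DecorrelationReport, Ensemble, OverlapReport, RunRecord

__all__ = ["save_run", "load_run", "write_summary_csv"]

_FORMAT_VERSION = 1


def save_run(run: RunRecord, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["seed"] = run.seed
        f.attrs["log_Z_ratio"] = run.log_Z_ratio
        f.create_dataset("schedule", data=np.asarray(run.schedule, dtype=float))
        steps = f.create_group("steps")
        for i in range(run.n_steps):
            g = steps.create_group(f"{i:04d}")
            g.attrs["lambda"] = run.schedule[i + 1]
            g.attrs["r_ess"] = run.step_overlaps[i].r_ess
            g.attrs["r_min"] = run.step_overlaps[i].r_min
            g.attrs["tau"] = run.step_decorrelation[i].tau
            g.attrs["r_tau"] = run.step_decorrelation[i].r_tau
            g.attrs["degenerate"] = run.step_decorrelation[i].degenerate
            g.attrs["mean_weight"] = run.step_weight_means[i]
            if run.step_distinct_ancestors:
                g.attrs["distinct_ancestors"] = run.step_distinct_ancestors[i]
        fin = f.create_group("final")
        fin.create_dataset("coordinates", data=run.final_ensemble.coords)
        fin.create_dataset("ancestor_ids", data=run.final_ensemble.ancestor_ids)
        if run.final_ensemble.energies is not None:
            fin.create_dataset("energies", data=run.final_ensemble.energies)
        if run.final_decorrelation is not None:
            fin.attrs["tau"] = run.final_decorrelation.tau
            fin.attrs["r_tau"] = run.final_decorrelation.r_tau
            fin.attrs["degenerate"] = run.final_decorrelation.degenerate


def load_run(path) -> RunRecord:
    with h5py.File(Path(path), "r") as f:
        schedule = list(np.asarray(f["schedule"]))
        steps = f["steps"]
        overlaps, decors, means, distinct = [], [], [], []
        for key in sorted(steps.keys()):
            g = steps[key]
            overlaps.append(
                OverlapReport(r_ess=float(g.attrs["r_ess"]), r_min=float(g.attrs["r_min"]))
            )
            decors.append(
                DecorrelationReport(
                    tau=int(g.attrs["tau"]),
                    r_tau=float(g.attrs["r_tau"]),
                    degenerate=bool(g.attrs["degenerate"]),
                )
            )
            means.append(float(g.attrs["mean_weight"]))
            if "distinct_ancestors" in g.attrs:
                distinct.append(int(g.attrs["distinct_ancestors"]))
        fin = f["final"]
        ensemble = Ensemble(
            np.asarray(fin["coordinates"]),
            lam=1.0,
            ancestor_ids=np.asarray(fin["ancestor_ids"]),
            energies=np.asarray(fin["energies"]) if "energies" in fin else None,
        )
        final_dec = None
        if "tau" in fin.attrs:
            final_dec = DecorrelationReport(
                tau=int(fin.attrs["tau"]),
                r_tau=float(fin.attrs["r_tau"]),
                degenerate=bool(fin.attrs["degenerate"]),
            )
        return RunRecord(
            schedule=schedule,
            step_overlaps=overlaps,
            step_decorrelation=decors,
            step_weight_means=means,
            log_Z_ratio=float(np.sum(np.log(means))),
            final_ensemble=ensemble,
            seed=int(f.attrs["seed"]),
            final_decorrelation=final_dec,
            step_distinct_ancestors=distinct,
        )


def write_summary_csv(run: RunRecord, path) -> None:
    run.summary_frame().to_csv(Path(path), index=False, float_format="%.12g")
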