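"""End-to-end orchestration: simulate -> process -> dwell -> fit -> rank ->
report, with per-stage seeds, per-stage counts and a run manifest.

Every artifact is plain TSV/JSON and carries the configuration hash, so a
run is reproducible byte-for-byte from its config and master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from zmwbind import io as zio
from zmwbind import table1_preset
from zmwbind.config import RunConfig
from zmwbind.dwells import (
    analysis_view,
    bound_probability,
    dwell_correlations,
    extract_dwells,
    fit_exp_mixture,
    lr_component_test,
    per_molecule_heterogeneity,
)
from zmwbind.fit import (
    cohort_from_idealized,
    encode_cohort,
    fit_model_global,
    fit_report,
    rank_models,
    resimulate_and_compare,
)
from zmwbind.process import fit_snr_distribution, process_trace
from zmwbind.simulate import simulate_cohort

STAGE_VERSION = "1"


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial results are in the run manifest."""


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    The manifest records per-stage counts (molecules generated, accepted,
    rejected, events, fits) and timings; a stage failure aborts with the
    partial manifest written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    cfg.save(out / "config.yaml")
    manifest: dict = {"config_hash": chash, "stage_version": STAGE_VERSION, "stages": {}}

    def record(stage, **kw):
        manifest["stages"][stage] = {"config_hash": chash, **kw}
        zio.write_json(manifest, out / "manifest.json")

    try:
        if "simulate" in cfg.stages:
            t0 = time.time()
            model = table1_preset(cfg.sim_model)
            traces = simulate_cohort(
                model, cfg.concentrations, cfg.n_per_conc, cfg.duration,
                seed=cfg.stage_seed("simulate"), bleach_mean=cfg.bleach_mean,
                snr=cfg.snr, crosstalk=cfg.crosstalk,
                frame_period=cfg.frame_period,
            )
            zio.write_cohort(traces, out / "traces")
            record("simulate", n_molecules=len(traces), seconds=round(time.time() - t0, 2))

        if "process" in cfg.stages:
            t0 = time.time()
            traces = zio.read_cohort(out / "traces" / "manifest.tsv", cfg.frame_period)
            seed0 = cfg.stage_seed("process")
            ideals = [
                process_trace(ts, alpha=cfg.crosstalk,
                              snr_threshold=cfg.snr_threshold, seed=seed0 + i)
                for i, ts in enumerate(traces)
            ]
            zio.write_idealizations(ideals, out / "idealized")
            accepted = [it for it in ideals if it.accepted]
            snrs = [it.snr for it in ideals if it.snr > 0 and np.isfinite(it.snr)]
            if len(snrs) >= 20:
                sd = fit_snr_distribution(snrs, cfg.snr_threshold)
                zio.write_json(asdict_safe(sd), out / "snr_distribution.json")
            record("process", n_in=len(ideals), n_accepted=len(accepted),
                   n_rejected=len(ideals) - len(accepted),
                   seconds=round(time.time() - t0, 2))

        if "dwell" in cfg.stages:
            t0 = time.time()
            ideals = zio.read_idealizations(out / "idealized" / "qc.tsv", cfg.frame_period)
            dw = extract_dwells(ideals, cfg.dead_time, cfg.frame_period)
            dw.to_csv(out / "dwells.tsv", sep="\t", index=False)
            av = analysis_view(dw)
            seed_d = cfg.stage_seed("dwell")
            fits = {}
            hist_rows = []
            for cls in ("unbound", "bound"):
                d = av.loc[av.state_class == cls, "duration_s"]
                if len(d) >= 10:
                    f1 = fit_exp_mixture(d, 1, cfg.dead_time, seed=seed_d,
                                         quantization=cfg.frame_period)
                    f2 = fit_exp_mixture(d, 2, cfg.dead_time, seed=seed_d,
                                         quantization=cfg.frame_period,
                                         compute_ci=True)
                    fits[cls] = {
                        "mono": mixture_doc(f1), "bi": mixture_doc(f2),
                        "p_mono_vs_bi": lr_component_test(f1, f2),
                    }
                    # log-binned histogram export, 15 bins per decade
                    span = np.log10(d.max() / d.min()) if d.max() > d.min() else 1
                    edges = np.geomspace(d.min(), d.max() * (1 + 1e-9),
                                         max(int(span * 15), 5) + 1)
                    counts, _ = np.histogram(d, bins=edges)
                    for lo, hi, n_ev in zip(edges[:-1], edges[1:], counts):
                        hist_rows.append({"state_class": cls, "bin_lo_s": lo,
                                          "bin_hi_s": hi, "count": int(n_ev)})
            zio.write_json(fits, out / "dwell_fits.json")
            if hist_rows:
                pd.DataFrame(hist_rows).to_csv(out / "dwell_histograms.tsv",
                                               sep="\t", index=False,
                                               float_format="%.6g")
            try:
                curve = bound_probability(ideals)
                zio.write_json(
                    {"Bmax": curve.bmax, "Kd_M": curve.kd,
                     "concentrations_M": curve.concentrations,
                     "bound_probability": curve.bound_probabilities},
                    out / "binding_curve.json")
            except ValueError as e:
                zio.write_json({"error": str(e)}, out / "binding_curve.json")
            # heterogeneity diagnostics are per concentration: pooling
            # across concentrations would fake same-class correlations
            # (unbound dwells scale with ligand)
            het_doc = {}
            pm_tables = []
            for conc, dwc in dw.groupby("concentration_M"):
                try:
                    het = per_molecule_heterogeneity(dwc)
                except ValueError as e:
                    het_doc[f"{conc:g}"] = {"error": str(e)}
                    continue
                pm = het.per_molecule.assign(concentration_M=conc)
                pm_tables.append(pm)
                corr = {**(dwell_correlations(dwc, 1) or {}),
                        **(dwell_correlations(dwc, 2) or {})}
                het_doc[f"{conc:g}"] = {
                    "delta_bic": het.delta_bic, "ashman_d": het.ashman_d,
                    "modality": het.modality, "correlations": corr}
            if pm_tables:
                pd.concat(pm_tables).to_csv(out / "per_molecule.tsv",
                                            sep="\t", index=False)
            zio.write_json(het_doc, out / "heterogeneity.json")
            record("dwell", n_events_raw=len(dw), n_events_analysis=len(av),
                   seconds=round(time.time() - t0, 2))

        fits_list = []
        if "fit" in cfg.stages:
            t0 = time.time()
            ideals = zio.read_idealizations(out / "idealized" / "qc.tsv", cfg.frame_period)
            cohort = cohort_from_idealized(ideals, cfg.frame_period)
            enc = encode_cohort(cohort)
            seed_f = cfg.stage_seed("fit")
            for mid in cfg.fit_models:
                mf = fit_model_global(table1_preset(mid), enc, cfg.dead_time,
                                      n_starts=cfg.n_starts, seed=seed_f)
                (out / f"fit_model{mid}.json").write_text(fit_report(mf))
                fits_list.append(mf)
            record("fit", n_models=len(fits_list), n_molecules=enc.n_molecules,
                   seconds=round(time.time() - t0, 2))

        if "rank" in cfg.stages and fits_list:
            ranked = rank_models(fits_list)
            pd.DataFrame(
                [{"model_id": f.model_id, "logL": f.log_likelihood,
                  "n_parameters": f.n_parameters, "AIC": f.aic,
                  "delta_AIC": f.delta_aic} for f in ranked]
            ).to_csv(out / "model_ranking.tsv", sep="\t", index=False)
            best = ranked[0]
            ideals = zio.read_idealizations(out / "idealized" / "qc.tsv", cfg.frame_period)
            cohort = cohort_from_idealized(ideals, cfg.frame_period)
            cmp = resimulate_and_compare(best, cohort, seed=cfg.stage_seed("rank"),
                                         dead_time=cfg.dead_time)
            zio.write_json(cmp, out / "resimulation.json")
            record("rank", best_model=best.model_id)

        if "report" in cfg.stages:
            make_figures(out)
            record("report", done=True)
    except Exception as exc:  # noqa: BLE001 - abort with partial manifest
        record("FAILED", error=str(exc))
        raise StageFailure(str(exc)) from exc
    zio.write_json(manifest, out / "manifest.json")
    return out


def mixture_doc(f):
    doc = {"k": f.k, "taus_s": f.taus, "amplitudes": f.amplitudes,
           "logL": f.log_likelihood, "n": f.n, "reduced": f.reduced}
    if f.ci:
        doc["ci95"] = f.ci
    return doc


def asdict_safe(obj):
    from dataclasses import asdict, is_dataclass

    return asdict(obj) if is_dataclass(obj) else obj


# ---------------------------------------------------------------------------
# figures


def make_figures(run_dir) -> list[Path]:
    """Render the run's summary figures from its tables (skip missing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    made = []

    def save(fig, name):
        p = run_dir / name
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        made.append(p)

    bc = run_dir / "binding_curve.json"
    if bc.exists():
        doc = json.loads(bc.read_text())
        if "Kd_M" in doc:
            fig, ax = plt.subplots(figsize=(4, 3))
            c = np.asarray(doc["concentrations_M"])
            ax.semilogx(c * 1e6, doc["bound_probability"], "ko", label="data")
            cg = np.geomspace(c.min() / 3, c.max() * 3, 100)
            ax.semilogx(cg * 1e6, doc["Bmax"] / (1 + doc["Kd_M"] / cg), "r-",
                        label=f"Bmax={doc['Bmax']:.2f}, Kd={doc['Kd_M']*1e6:.2g} uM")
            ax.set_xlabel("ligand (uM)")
            ax.set_ylabel("bound probability")
            ax.legend(fontsize=7)
            save(fig, "fig_binding_curve.png")

    dwf = run_dir / "dwells.tsv"
    fits_f = run_dir / "dwell_fits.json"
    if dwf.exists():
        dw = pd.read_csv(dwf, sep="\t")
        av = dw[~dw.edge_flag & ~dw.subthreshold_flag]
        fits = json.loads(fits_f.read_text()) if fits_f.exists() else {}
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        for ax, cls in zip(axes, ("unbound", "bound")):
            d = av.loc[av.state_class == cls, "duration_s"]
            if len(d) == 0:
                continue
            bins = np.geomspace(d.min(), d.max() + 1e-9, _log_bins(d))
            ax.hist(d, bins=bins, color="0.7", density=True)
            if cls in fits:
                tg = np.geomspace(d.min(), d.max(), 200)
                for key, style in (("mono", "b--"), ("bi", "r-")):
                    doc = fits[cls][key]
                    taus = np.asarray(doc["taus_s"])
                    amps = np.asarray(doc["amplitudes"])
                    z = np.sum(amps * np.exp(-0.2 / taus))
                    f = sum(a * np.exp(-tg / t) / t for a, t in zip(amps, taus)) / z
                    ax.plot(tg, f, style, lw=1)
            ax.set_xscale("log")
            ax.set_title(cls)
            ax.set_xlabel("dwell (s)")
        save(fig, "fig_dwell_histograms.png")

    pm = run_dir / "per_molecule.tsv"
    if pm.exists():
        t = pd.read_csv(pm, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 3.5))
        edges = np.geomspace(0.1, 100, 30)
        h = ax.hist2d(t.mean_unbound_s, t.mean_bound_s, bins=[edges, edges],
                      cmap="viridis")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("mean unbound (s)")
        ax.set_ylabel("mean bound (s)")
        fig.colorbar(h[3], ax=ax, label="molecules")
        save(fig, "fig_per_molecule_contour.png")

    rk = run_dir / "model_ranking.tsv"
    if rk.exists():
        t = pd.read_csv(rk, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(t.model_id.astype(str), t.delta_AIC, color="0.4")
        ax.set_xlabel("model")
        ax.set_ylabel(r"$\Delta$AIC")
        save(fig, "fig_delta_aic.png")

    rs = run_dir / "resimulation.json"
    if rs.exists() and dwf.exists():
        doc = json.loads(rs.read_text())
        groups = doc.get("per_group", {})
        if groups:
            fig, ax = plt.subplots(figsize=(4, 3))
            names = list(groups)
            ax.bar(range(len(names)), [groups[k]["ks"] for k in names], color="0.4")
            ax.set_xticks(range(len(names)))
            ax.set_xticklabels(names, rotation=90, fontsize=6)
            ax.set_ylabel("KS distance (obs vs resim)")
            save(fig, "fig_resimulation_ks.png")
    return made


def _log_bins(d, per_decade: int = 15) -> int:
    span = np.log10(d.max() / max(d.min(), 1e-3))
    return max(int(span * per_decade), 5)
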