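"""End-to-end orchestration: simulate -> calibrate -> quantify -> fit ->
summarize -> shape -> library -> model, with one master seed feeding
named per-stage substreams so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, affinity, chipsim, quantify, refdata, shape, shapemodel, sitelib

log = logging.getLogger(__name__)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
    )


@dataclass
class RunConfig:
    seed: int = 0
    layout_mode: str = chipsim.FOUR_SECTION
    proteins: list = field(default_factory=lambda: list(refdata.REFERENCE_KD_PANEL))
    dilution_start: float = refdata.DILUTION_START_UM
    dilution_end: float = refdata.DILUTION_END_UM
    dilution_n: int = refdata.DILUTION_N
    protein_cv_low: float = 0.06
    protein_cv_high: float = 0.40
    snr: float = 100.0
    intensity_cv: float = 0.05
    kd_lower: float = refdata.KD_LOWER_LIMIT_UM
    kd_upper: float = refdata.KD_UPPER_LIMIT_UM
    shape_w: int = 5
    shape_k: int = 10
    shape_flank: int = 5
    genome_length: int = 120_000
    n_full_sites: int = 14
    n_half_sites: int = 160
    quota: dict = field(default_factory=lambda: {"A_only": 34, "B_only": 34, "both": 34, "accessible_unbound": 5})
    model_noise_frac: float = 0.10

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage, writing all artifacts plus a run log.

    Raises with the stage name on any failure; the same config and seed
    regenerate every file bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    run_log = [f"qpid {__version__} on python {platform.python_version()}", f"seed {config.seed}"]
    stage = "init"
    try:
        # --- shape table ---------------------------------------------------
        stage = "shape-table"
        table = chipsim.synth_pentamer_table(stage_seed(config.seed, stage))
        table.to_tsv(out / "pentamers.tsv")

        # --- calibration ---------------------------------------------------
        stage = "calibration"
        points = chipsim.simulate_calibration_points(
            refdata.CAL_SLOPE_RFU_PER_UM,
            refdata.CAL_INTERCEPT_RFU,
            refdata.CAL_N_POINTS,
            refdata.CAL_CONC_MIN_UM,
            refdata.CAL_CONC_MAX_UM,
            cv=0.05,
            seed=stage_seed(config.seed, stage),
        )
        points.to_csv(out / "calibration_points.tsv", sep="\t", index=False)
        curve = quantify.fit_calibration(points)
        curve.to_json(out / "curve.json")
        run_log.append(f"calibration slope={curve.slope:.1f} intercept={curve.intercept:.1f} r2={curve.r_squared:.5f}")

        # --- chip simulation ----------------------------------------------
        stage = "simulate-chip"
        layout = chipsim.ChipLayout(
            mode=config.layout_mode,
            oligos=tuple(range(1, 33)),
            proteins=tuple(config.proteins),
        )
        truths = refdata.reference_truths(proteins=list(dict.fromkeys(config.proteins)))
        series = chipsim.make_dilution_series(config.dilution_start, config.dilution_end, config.dilution_n)
        noise = chipsim.NoiseSpec(
            protein_cv_range=(config.protein_cv_low, config.protein_cv_high),
            snr=config.snr,
            intensity_cv=config.intensity_cv,
            seed=stage_seed(config.seed, stage),
        )
        scan = chipsim.simulate_chip(layout, truths, series, noise, curve)
        quantify.write_scan_table(scan, out / "scan.tsv")

        # --- quantify + fit ------------------------------------------------
        stage = "quantify"
        occupancy = quantify.quantify_scan(scan, curve)
        occupancy.to_csv(out / "occupancy.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "fit"
        fits = affinity.fit_all(quantify.quantify_scan(scan, curve, aggregate=False))
        affinity.write_kd_table(fits, out / "kd.tsv")
        n_cens = sum(f.status != affinity.QUANTITATIVE for f in fits)
        run_log.append(f"fit: {len(fits)} series, {n_cens} censored/failed")

        # --- group summaries -----------------------------------------------
        stage = "summarize"
        by_key = {(f.protein, f.oligo): f for f in fits}
        groups: dict[str, list[int]] = {}
        for oligo, site in refdata.OLIGO_SITE_TYPE.items():
            groups.setdefault(site, []).append(oligo)
        rows = []
        for protein in dict.fromkeys(config.proteins):
            for site, oligos in groups.items():
                kds = [
                    by_key[(protein, o)].kd
                    if by_key[(protein, o)].status == affinity.QUANTITATIVE
                    else None
                    for o in oligos
                    if (protein, o) in by_key
                ]
                summ = affinity.summarize_group(kds, label=f"{protein}/{site}")
                if summ is not None:
                    rows.append(
                        {"protein": protein, "site": site, "mean_kd_uM": summ.mean_kd,
                         "sd_uM": summ.spread, "n": summ.n, "n_censored": summ.n_censored}
                    )
        pd.DataFrame(rows).to_csv(out / "summaries.tsv", sep="\t", index=False, float_format="%.6g")

        # --- synthetic genome + library ------------------------------------
        stage = "simulate-genome"
        genome = chipsim.synth_genome_and_peaks(
            config.genome_length,
            config.n_full_sites,
            config.n_half_sites,
            seed=stage_seed(config.seed, stage),
        )
        genome.write(out / "genome")

        stage = "design-library"
        pools = sitelib.harvest_candidates(
            {genome.chrom: genome.sequence},
            sitelib.PeakSet(genome.chip_a),
            sitelib.PeakSet(genome.chip_b),
            sitelib.PeakSet(genome.dnase),
            "CRE_half",
        )
        library = sitelib.design_library(pools, config.quota, seed=stage_seed(config.seed, stage))
        sitelib.write_library(library, out / "library")
        run_log.append(f"library: {len(library)} entries from pools " +
                       str({c: len(p) for c, p in pools.items()}))

        # --- shape vectors + distances -------------------------------------
        stage = "shape"
        vectors = {
            e.entry_id: shape.build_feature_vector(
                e.sequence, e.core_offset + 1, config.shape_w, config.shape_k, table
            )
            for e in library
        }
        shape.write_vectors(vectors, config.shape_w, config.shape_k, out / "vectors.tsv")
        profile = shape.ReferenceProfile(
            core_width=config.shape_w,
            flank=config.shape_k,
            values=np.mean([v.values for v in vectors.values()], axis=0),
            n_sites=len(vectors),
            source="library-mean",
        )
        dist_rows = []
        for name, vec in vectors.items():
            d = shape.normalized_distance(vec, profile, scope="per-feature")
            d["overall"] = shape.normalized_distance(vec, profile, scope="overall")
            dist_rows.append({"id": name, **d})
        pd.DataFrame(dist_rows).to_csv(out / "distances.tsv", sep="\t", index=False, float_format="%.5f")

        # --- shape regression on planted affinities ------------------------
        stage = "model"
        positions = shapemodel.default_flank_positions(config.shape_w, config.shape_k, config.shape_flank)
        X = shapemodel.build_design_matrix(vectors, positions, config.shape_w, config.shape_k)
        rng = np.random.default_rng(stage_seed(config.seed, stage))
        planted_a = _planted_model(X, {"MGW@8": -1.2, "Roll@15": 0.10, "HelT@5": 0.05})
        planted_b = _planted_model(X, {"MGW@8": -0.6, "ProT@16": 0.04, "Roll@15": 0.08})
        noise_a = config.model_noise_frac * planted_a.affinities(X).std()
        noise_b = config.model_noise_frac * planted_b.affinities(X).std()
        y_a = planted_a.affinities(X) + rng.normal(0, noise_a, len(X))
        y_b = planted_b.affinities(X) + rng.normal(0, noise_b, len(X))
        # small demo libraries can drop below rows >= columns + 2; the ridge
        # fallback is flagged in the serialized models when that happens
        model_a = shapemodel.fit_model(X, y_a, response_label="affinity_A", allow_ridge=True)
        model_b = shapemodel.fit_model(X, y_b, response_label="affinity_B", allow_ridge=True)
        model_d = shapemodel.fit_difference_model(X, y_a, y_b, allow_ridge=True)
        model_a.to_json(out / "model_a.json")
        model_b.to_json(out / "model_b.json")
        model_d.to_json(out / "model_difference.json")
        shapemodel.rank_features(model_d).to_csv(
            out / "feature_ranks.tsv", sep="\t", index=False, float_format="%.5f"
        )
        run_log.append(
            f"models: r2 A={model_a.r_squared:.3f} B={model_b.r_squared:.3f} diff={model_d.r_squared:.3f}"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text("\n".join(run_log) + "\n")
    render_report(out)
    return out


def _planted_model(X: pd.DataFrame, weights: dict) -> chipsim.PlantedShapeModel:
    """Planted linear model with intercept chosen to keep affinities positive."""
    base = sum(w * X[c].mean() for c, w in weights.items())
    return chipsim.PlantedShapeModel(intercept=float(2.0 - base), weights=weights)


def render_report(run_dir: str | Path) -> Path:
    """Human-readable report: Kd grid with '-' for censored entries plus
    the group summaries.  Regeneration is idempotent."""
    run = Path(run_dir)
    kd_path = run / "kd.tsv"
    if not kd_path.exists():
        raise FileNotFoundError(f"incomplete run: {kd_path} missing")
    kd = pd.read_csv(kd_path, sep="\t")

    def show(row):
        if row["status"] in (affinity.CENSORED_WEAK, affinity.FAILED):
            return "-"
        return f"{row['kd_uM']:.3g}"

    kd["display"] = kd.apply(show, axis=1)
    grid = kd.pivot(index="oligo", columns="protein", values="display")
    lines = ["Dissociation constants (uM); '-' marks interactions above the 50 uM limit", ""]
    lines.append(grid.to_string())
    summ_path = run / "summaries.tsv"
    if summ_path.exists():
        summ = pd.read_csv(summ_path, sep="\t")
        lines += ["", "Group summaries (mean +/- population SD, uM)", ""]
        for r in summ.itertuples():
            lines.append(f"  {r.protein:<12} {r.site:<8} {r.mean_kd_uM:.3g} +/- {r.sd_uM:.3g}  (n={r.n})")
    path = run / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
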