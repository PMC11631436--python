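"""End-to-end analysis pipelines.

Two analyses mirror the structure of an inter-/intraspecific molar
study:

* **interspecific** — per jaw: molar triples, OLS + PGLS log-log
  allometry of each tooth against the row, Blomberg's K (row size,
  per-tooth sizes, both ratios) with permutation p-values, ancestral
  states of log row size, a PGLS fit of M3/M1 on M2/M1 with
  inhibitory-cascade consistency flags, morphospace calls, and an
  M2-share summary;
* **intraspecific** — per jaw: pattern census, OLS + lagSAR allometry,
  a lagSAR cascade fit, and the M2-share summary.

``run_demo`` generates synthetic inputs (written to disk and re-read
through the real I/O path) and runs both analyses, so the whole surface
is exercisable with no external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry as allom
from . import ic_model, io_tables, molar_metrics, phylo, spatial, synthetic

logger = logging.getLogger(__name__)

JAW_NAME = {"lower": "mandible", "upper": "maxilla"}


def _config_stamp(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: dict) -> str:
    seed = config.get("seed", "none")
    return f"molaric results | seed={seed} | config_hash={_config_stamp(config)}"


def m2_share_summary(triples: pd.DataFrame) -> pd.DataFrame:
    """Mean / min / max M2 share (percent) per jaw, with the group
    attaining each extreme."""
    rows = []
    for jaw, sub in triples.groupby("jaw", sort=True):
        pct = 100.0 * sub["m2_share"]
        imin, imax = pct.idxmin(), pct.idxmax()
        rows.append(
            {
                "jaw": jaw,
                "mean_pct": pct.mean(),
                "min_pct": pct[imin],
                "min_group": sub.loc[imin, "group_id"],
                "max_pct": pct[imax],
                "max_group": sub.loc[imax, "group_id"],
            }
        )
    return pd.DataFrame(rows)


def run_interspecific(
    measurements: pd.DataFrame,
    tree: io_tables.PhyloTree,
    config: dict | None = None,
) -> dict:
    """Interspecific analysis bundle (see module docstring).

    ``measurements`` is a validated diameter table; ``tree`` must cover
    the groups (it is pruned per jaw to the groups with complete
    triples; groups absent from the tree are dropped and logged).
    """
    config = dict(config or {})
    mode = config.get("aggregation", "mean_diameters")
    n_perm = int(config.get("n_perm", 999))
    seed = int(config.get("seed", 0))

    triples = molar_metrics.aggregate_group(measurements, mode=mode)
    if triples.empty:
        raise io_tables.ValidationError("no complete molar triples to analyze")

    allometry_rows, k_rows, ic_rows, morpho_rows, anc_frames = [], [], [], [], []
    for jaw, sub in triples.groupby("jaw", sort=True):
        in_tree = sub["group_id"].isin(tree.tip_labels)
        if not in_tree.all():
            dropped = sorted(sub.loc[~in_tree, "group_id"])
            logger.warning("jaw %s: groups missing from tree dropped: %s", jaw, dropped)
            sub = sub[in_tree]
        if len(sub) < 4:
            raise io_tables.ValidationError(
                f"jaw {jaw}: only {len(sub)} groups shared with the tree"
            )
        sub = sub.reset_index(drop=True)
        jtree = io_tables.prune_to_common(tree, sub["group_id"])
        cov = phylo.bm_covariance(jtree, list(sub["group_id"]))

        for method in ("OLS", "PGLS"):
            for tooth in allom.TEETH:
                allometry_rows.append(
                    allom.loglog_allometry(sub, tooth, method, cov=cov).as_dict()
                )

        traits = {
            "log_row": np.log(sub["row"]),
            "log_M1": np.log(sub["a1"]),
            "log_M2": np.log(sub["a2"]),
            "log_M3": np.log(sub["a3"]),
            "r2_M2_M1": sub["r2"],
            "r3_M3_M1": sub["r3"],
        }
        for name, values in traits.items():
            series = pd.Series(values.to_numpy(dtype=float), index=list(sub["group_id"]))
            k, p = phylo.phylosignal_test(jtree, series, n_perm=n_perm, seed=seed + 17)
            k_rows.append({"jaw": jaw, "trait": name, "K": k, "p_perm": p})

        anc = phylo.ancestral_states(
            jtree,
            pd.Series(np.log(sub["row"]).to_numpy(), index=list(sub["group_id"])),
        )
        anc_frames.append(
            pd.DataFrame({"jaw": jaw, "node_id": anc.index, "log_row_estimate": anc.values})
        )

        fit = ic_model.fit_ic_line(sub, method="PGLS", cov=cov)
        ic_rows.append(_ic_fit_row(jaw, fit))
        for t in molar_metrics.triples_from_frame(sub):
            call = ic_model.classify_morphospace(t)
            morpho_rows.append(vars(call))

    return {
        "triples": triples,
        "allometry": pd.DataFrame(allometry_rows),
        "phylo_signal": pd.DataFrame(k_rows),
        "ancestral_states": pd.concat(anc_frames, ignore_index=True),
        "ic_fit": pd.DataFrame(ic_rows),
        "morphospace": pd.DataFrame(morpho_rows),
        "m2_share": m2_share_summary(triples),
    }


def run_intraspecific(
    measurements: pd.DataFrame,
    coordinates: pd.DataFrame,
    config: dict | None = None,
) -> dict:
    """Intraspecific (population) analysis bundle (see module docstring)."""
    config = dict(config or {})
    mode = config.get("aggregation", "mean_diameters")
    style = config.get("weight_style", "row_standardized")
    epsilon_km = float(config.get("epsilon_km", 1.0))
    tol = float(config.get("pattern_tol", 0.0))

    triples = molar_metrics.aggregate_group(measurements, mode=mode)
    if triples.empty:
        raise io_tables.ValidationError("no complete molar triples to analyze")

    census_rows, allometry_rows, ic_rows, morpho_rows = [], [], [], []
    for jaw, sub in triples.groupby("jaw", sort=True):
        have_coords = sub["group_id"].isin(coordinates["group_id"])
        if not have_coords.all():
            dropped = sorted(sub.loc[~have_coords, "group_id"])
            logger.warning("jaw %s: populations without coordinates dropped: %s", jaw, dropped)
            sub = sub[have_coords]
        sub = sub.reset_index(drop=True)
        census = molar_metrics.pattern_census(sub, tol=tol)
        census.insert(0, "jaw", jaw)
        census_rows.append(census)

        locs = (
            coordinates.set_index("group_id")
            .loc[list(sub["group_id"])]
            .reset_index()
        )
        weights = spatial.inverse_distance_weights(locs, style=style, epsilon_km=epsilon_km)

        for method in ("OLS", "lagSAR"):
            for tooth in allom.TEETH:
                allometry_rows.append(
                    allom.loglog_allometry(sub, tooth, method, weights=weights).as_dict()
                )

        fit = ic_model.fit_ic_line(sub, method="lagSAR", weights=weights)
        ic_rows.append(_ic_fit_row(jaw, fit))
        for t in molar_metrics.triples_from_frame(sub):
            morpho_rows.append(vars(ic_model.classify_morphospace(t, tol=tol)))

    return {
        "triples": triples,
        "pattern_census": pd.concat(census_rows, ignore_index=True),
        "allometry": pd.DataFrame(allometry_rows),
        "ic_fit": pd.DataFrame(ic_rows),
        "morphospace": pd.DataFrame(morpho_rows),
        "m2_share": m2_share_summary(triples),
    }


def _ic_fit_row(jaw: str, fit: ic_model.ICFitResult) -> dict:
    r = fit.result
    return {
        "jaw": jaw,
        "method": r.method,
        "slope": r.slope,
        "slope_lo": r.ci95_slope[0],
        "slope_hi": r.ci95_slope[1],
        "intercept": r.intercept,
        "intercept_lo": r.ci95_intercept[0],
        "intercept_hi": r.ci95_intercept[1],
        "r2": r.r2,
        "slope_consistent": fit.slope_consistent,
        "intercept_consistent": fit.intercept_consistent,
    }


# ---------------------------------------------------------------------------
# Demo / config-driven entry points


def _demo_measurements(triples: pd.DataFrame, group_type: str) -> pd.DataFrame:
    """Back out a diameter table from areas (md = bl = sqrt(area)) so
    demo data flow through the real measurement reader/aggregator."""
    rows = []
    for t in triples.itertuples():
        for tooth, area in (("M1", t.a1), ("M2", t.a2), ("M3", t.a3)):
            d = float(np.sqrt(area))
            rows.append(
                {
                    "group_id": t.group_id, "group_type": group_type,
                    "jaw": t.jaw, "tooth": tooth, "md": d, "bl": d,
                }
            )
    return pd.DataFrame(rows)


def run_demo(seed: int, out_dir, n_taxa: int = 21, n_populations: int = 56) -> dict:
    """Generate synthetic inputs, write them, re-read them through the
    I/O layer, and run both analyses end to end.

    Returns ``{"interspecific": ..., "intraspecific": ...,
    "inputs": {...paths...}}`` and writes all tidy CSVs to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {"seed": seed, "n_taxa": n_taxa, "n_populations": n_populations}

    # interspecific fixture: BM-evolving log sizes on a Yule tree
    cfg_sp = synthetic.SyntheticConfig(seed=seed, n_taxa=n_taxa)
    bm_lower, tree, _ = synthetic.gen_bm_dataset(cfg_sp)
    bm_upper, _, _ = synthetic.gen_bm_dataset(
        synthetic.SyntheticConfig(seed=seed + 1000, n_taxa=n_taxa), tree=tree
    )
    sp_triples = pd.concat(
        [
            _bm_to_triples(bm_lower, "lower"),
            _bm_to_triples(bm_upper, "upper"),
        ],
        ignore_index=True,
    )
    sp_meas = _demo_measurements(sp_triples, "species")
    meas_path = out / "demo_species_measurements.csv"
    tree_path = out / "demo_tree.nwk"
    sp_meas.to_csv(meas_path, index=False)
    io_tables.write_newick(tree, tree_path)

    # intraspecific fixture: spatially structured populations
    cfg_pop = synthetic.SyntheticConfig(seed=seed + 2000, n_groups=n_populations)
    pop_lower, locs, _ = synthetic.gen_population_dataset(cfg_pop, jaw="lower")
    pop_upper, _, _ = synthetic.gen_population_dataset(
        synthetic.SyntheticConfig(seed=seed + 3000, n_groups=n_populations), jaw="upper"
    )
    pop_triples = pd.concat([pop_lower, pop_upper], ignore_index=True)
    pop_meas = _demo_measurements(pop_triples, "population")
    pop_path = out / "demo_population_measurements.csv"
    coords_path = out / "demo_coordinates.csv"
    pop_meas.to_csv(pop_path, index=False)
    locs.to_csv(coords_path, index=False)

    measurements = io_tables.read_measurements(meas_path)
    tree_in = io_tables.read_newick(tree_path)
    inter = run_interspecific(measurements, tree_in, {"seed": seed, "n_perm": 199})

    pop_measurements = io_tables.read_measurements(pop_path)
    coords = io_tables.read_coordinates(coords_path)
    intra = run_intraspecific(pop_measurements, coords, {"seed": seed})

    header = _header(config)
    for name, df in {
        "interspecific_triples": inter["triples"],
        "interspecific_allometry": inter["allometry"],
        "interspecific_phylo_signal": inter["phylo_signal"],
        "interspecific_ancestral_states": inter["ancestral_states"],
        "interspecific_ic_fit": inter["ic_fit"],
        "interspecific_morphospace": inter["morphospace"],
        "interspecific_m2_share": inter["m2_share"],
        "intraspecific_triples": intra["triples"],
        "intraspecific_pattern_census": intra["pattern_census"],
        "intraspecific_allometry": intra["allometry"],
        "intraspecific_ic_fit": intra["ic_fit"],
        "intraspecific_morphospace": intra["morphospace"],
        "intraspecific_m2_share": intra["m2_share"],
    }.items():
        io_tables.write_tidy_results(df, out / f"{name}.csv", header_comment=header)

    return {
        "interspecific": inter,
        "intraspecific": intra,
        "inputs": {
            "measurements": meas_path,
            "tree": tree_path,
            "population_measurements": pop_path,
            "coordinates": coords_path,
        },
    }


def _bm_to_triples(bm: pd.DataFrame, jaw: str) -> pd.DataFrame:
    areas = np.exp(bm[["log_a1", "log_a2", "log_a3"]].to_numpy())
    records = [
        molar_metrics.MolarTriple(str(gid), jaw, *areas[i])
        for i, gid in enumerate(bm.index)
    ]
    return synthetic._triples_frame(records)


def run_all(config_path) -> int:
    """Run the analyses described by a YAML config file.

    Top-level keys: ``seed`` (int), ``out`` (directory), optional
    ``demo: true``, and per-analysis sections::

        interspecific: {measurements: X.csv, tree: T.nwk}
        intraspecific: {measurements: Y.csv, coords: C.csv}

    Returns a process exit status (0 on success).
    """
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    seed = int(config.get("seed", 0))
    out = Path(config.get("out", "molaric_results"))
    out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    status = 0
    try:
        if config.get("demo"):
            run_demo(seed, out)
        if "interspecific" in config:
            sec = config["interspecific"]
            measurements = io_tables.read_measurements(sec["measurements"])
            tree = io_tables.read_newick(sec["tree"])
            res = run_interspecific(measurements, tree, {"seed": seed, **sec})
            for name, df in res.items():
                io_tables.write_tidy_results(
                    df, out / f"interspecific_{name}.csv", header_comment=header
                )
        if "intraspecific" in config:
            sec = config["intraspecific"]
            measurements = io_tables.read_measurements(sec["measurements"])
            coords = io_tables.read_coordinates(sec["coords"])
            res = run_intraspecific(measurements, coords, {"seed": seed, **sec})
            for name, df in res.items():
                io_tables.write_tidy_results(
                    df, out / f"intraspecific_{name}.csv", header_comment=header
                )
    except Exception:
        logger.exception("pipeline stage failed; partial results kept in %s", out)
        status = 1
    return status
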