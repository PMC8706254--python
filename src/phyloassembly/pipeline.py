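"""End-to-end orchestration: align -> alpha -> beta -> null models ->
partition -> NCM/SAD -> Mantel, from one declarative config.

Every stochastic stage consumes a substream derived from the global seed
and a stable stage name, so runs are bit-reproducible and disabling one
stage never perturbs another's randomness. All tabular outputs are TSV
with a fixed float format; summaries are JSON with sorted keys — a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alpha import alpha_table
from .beta import bray_curtis, weighted_unifrac, beta_mntd
from .correlations import env_distance, geo_distance, mantel
from .io import CountTable, read_count_table, read_metadata, read_tree, align_inputs
from .matrices import PairwiseMatrix
from .ncm import fit_ncm, ncm_per_group, fit_lognormal_sad, fit_geometric_sad
from .nullmodels import beta_nti, raup_crick_bray
from .partition import classify_pairs, partition_fractions
from .rng import substream_seed
from .simulate import simulate_scenario

logger = logging.getLogger(__name__)

ALL_STAGES = ("alpha", "beta", "nullmodels", "partition", "ncm", "sad", "mantel")


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Either ``inputs`` (paths to table/tree/metadata) or ``simulate`` (an
    assembly-scenario block passed to :func:`simulate_scenario`) must be
    given. Stage parameter defaults mirror the field conventions: 1000
    NTI randomizations, 999 betaNTI/Raup-Crick replicates, 9999 Mantel and
    999 partial-Mantel permutations, thresholds 2 and 0.95.
    """

    seed: int = 0
    out_dir: str = "phyloassembly_out"
    inputs: dict | None = None
    simulate: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    alpha: dict = field(default_factory=lambda: {"n_null": 1000})
    beta: dict = field(default_factory=lambda: {"unifrac_normalized": True, "bmntd_weighted": True})
    nullmodels: dict = field(default_factory=lambda: {"n_null": 999, "weighted": True})
    partition: dict = field(default_factory=lambda: {"group_column": "layer", "scheme": "within_group"})
    ncm: dict = field(default_factory=lambda: {"group_column": "layer"})
    mantel: dict = field(default_factory=lambda: {"n_perm": 9999, "method": "pearson"})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            elif key == "stages":
                unknown = set(value) - set(ALL_STAGES)
                if unknown:
                    raise ValueError(f"unknown stage(s): {sorted(unknown)}")
                setattr(cfg, key, tuple(value))
            else:
                setattr(cfg, key, value)
        if cfg.inputs is None and cfg.simulate is None:
            raise ValueError("config needs either an 'inputs' or a 'simulate' block")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "inputs": self.inputs,
            "simulate": self.simulate,
            "stages": list(self.stages),
            "alpha": self.alpha,
            "beta": self.beta,
            "nullmodels": self.nullmodels,
            "partition": self.partition,
            "ncm": self.ncm,
            "mantel": self.mantel,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    out_dir: str
    manifest: list[str]
    warnings: list[str]
    config_hash: str
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "manifest": sorted(self.manifest),
            "warnings": self.warnings,
            "config_hash": self.config_hash,
            "version": self.version,
        }


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, manifest: list[str], cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Writes, per enabled stage: ``alpha.tsv``; ``bray_curtis.tsv`` /
    ``weighted_unifrac.tsv`` / ``beta_mntd.tsv``; ``bnti.tsv`` /
    ``rcbray.tsv`` + provenance; ``pair_classification.tsv`` /
    ``partition_summary.tsv``; ``ncm_fit.json`` / ``ncm_per_otu.tsv``;
    ``sad_fit.json`` / ``sad_octaves.tsv``; ``mantel.json`` — plus
    ``report.json`` listing every file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    notes: list[str] = []
    stage = "setup"

    def emit(name: str) -> Path:
        manifest.append(name)
        return out / name

    try:
        # ---- inputs ------------------------------------------------------
        if config.simulate is not None:
            sim = dict(config.simulate)
            regime = sim.pop("regime")
            scen = simulate_scenario(
                regime, seed=substream_seed(config.seed, "simulate"), **sim
            )
            table, tree, meta = scen.table, scen.tree, scen.metadata.set_index("sample_id")
            _write_json(scen.provenance, emit("simulation_provenance.json"))
            table.write(emit("table.tsv"))
            tree.write(str(emit("tree.nwk")))
            _write_tsv(meta, emit("metadata.tsv"))
        else:
            paths = config.inputs
            table = read_count_table(
                paths["table"], orientation=paths.get("orientation", "taxa_as_rows")
            )
            tree = read_tree(paths["tree"]) if paths.get("tree") else None
            meta = read_metadata(paths["metadata"]) if paths.get("metadata") else None

        n_taxa_before = table.n_taxa
        table, tree, meta = align_inputs(table, tree, meta)
        table = table.drop_empty_taxa()
        if table.n_taxa < n_taxa_before:
            notes.append(f"dropped {n_taxa_before - table.n_taxa} taxa during alignment")

        group_col = config.partition.get("group_column", "layer")
        grouping = None
        if meta is not None and group_col in meta.columns:
            grouping = meta[group_col].astype(str).to_dict()

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # ---- alpha ---------------------------------------------------
            if "alpha" in config.stages:
                stage = "alpha"
                df = alpha_table(
                    table,
                    tree,
                    n_null=config.alpha.get("n_null", 1000),
                    seed=substream_seed(config.seed, "alpha"),
                )
                _write_tsv(df, emit("alpha.tsv"))

            # ---- beta ----------------------------------------------------
            beta_mats: dict[str, PairwiseMatrix] = {}
            if "beta" in config.stages or "mantel" in config.stages:
                stage = "beta"
                beta_mats["bray_curtis"] = bray_curtis(table)
                if tree is not None:
                    beta_mats["weighted_unifrac"] = weighted_unifrac(
                        table, tree, normalized=config.beta.get("unifrac_normalized", True)
                    )
                    beta_mats["beta_mntd"] = beta_mntd(
                        table, tree, weighted=config.beta.get("bmntd_weighted", True)
                    )
                if "beta" in config.stages:
                    for name, mat in beta_mats.items():
                        mat.write(emit(f"{name}.tsv"))

            # ---- null models --------------------------------------------
            bnti_res = rc_res = None
            need_null = {"nullmodels", "partition"} & set(config.stages)
            if need_null or ("mantel" in config.stages and tree is not None):
                stage = "nullmodels"
                n_null = config.nullmodels.get("n_null", 999)
                weighted = config.nullmodels.get("weighted", True)
                if tree is not None:
                    bnti_res = beta_nti(
                        table, tree, n_null=n_null, weighted=weighted,
                        seed=substream_seed(config.seed, "beta_nti"),
                    )
                rc_res = raup_crick_bray(
                    table, n_null=n_null, seed=substream_seed(config.seed, "raup_crick")
                )
                if "nullmodels" in config.stages:
                    if bnti_res is not None:
                        bnti_res.bnti.write(emit("bnti.tsv"))
                    rc_res.rc.write(emit("rcbray.tsv"))
                    _write_json(
                        {
                            "n_null": n_null,
                            "weighted": weighted,
                            "seed": config.seed,
                            "n_flagged_bnti_pairs": (
                                bnti_res.n_flagged_pairs if bnti_res else None
                            ),
                        },
                        emit("nullmodels_provenance.json"),
                    )
                    if bnti_res and bnti_res.n_flagged_pairs:
                        notes.append(
                            f"{bnti_res.n_flagged_pairs} betaNTI pair(s) undefined (sd_null=0)"
                        )

            # ---- partition ----------------------------------------------
            if "partition" in config.stages and bnti_res is not None:
                stage = "partition"
                pairs = classify_pairs(bnti_res.bnti, rc_res.rc)
                _write_tsv(pairs, emit("pair_classification.tsv"), index=False)
                scheme = config.partition.get("scheme", "within_group")
                summary = partition_fractions(pairs, grouping, scheme=scheme)
                _write_tsv(summary, emit("partition_summary.tsv"))
                overall = partition_fractions(pairs, None, scheme="all_pairs")
                _write_tsv(overall, emit("partition_overall.tsv"))

            # ---- NCM -----------------------------------------------------
            if "ncm" in config.stages:
                stage = "ncm"
                fit = fit_ncm(table)
                _write_json(
                    {"group": "all", "m": fit.m, "r2": fit.r2, "N": fit.N, "d": fit.d,
                     "n_samples": fit.n_samples,
                     "partition_counts": fit.partition_counts.to_dict()},
                    emit("ncm_fit.json"),
                )
                _write_tsv(fit.per_otu, emit("ncm_per_otu.tsv"), index_label="taxon_id")
                if grouping is not None:
                    per_group = ncm_per_group(table, grouping)
                    _write_json(
                        {
                            g: {"m": f.m, "r2": f.r2, "N": f.N, "n_samples": f.n_samples}
                            for g, f in sorted(per_group.items())
                        },
                        emit("ncm_per_group.json"),
                    )

            # ---- SAD -----------------------------------------------------
            if "sad" in config.stages:
                stage = "sad"
                pooled = table.data.sum(axis=1).to_numpy()
                ln_fit = fit_lognormal_sad(pooled)
                geo_fit = fit_geometric_sad(pooled)
                _write_json(
                    {
                        "lognormal": {"S0": ln_fit.S0, "a": ln_fit.a,
                                      "modal_octave": ln_fit.modal_octave, "aic": ln_fit.aic},
                        "geometric": {"c": geo_fit.c, "theta": geo_fit.theta,
                                      "aic": geo_fit.aic},
                    },
                    emit("sad_fit.json"),
                )
                _write_tsv(
                    pd.DataFrame(
                        {"species": ln_fit.octave_counts, "lognormal_fit": ln_fit.fitted,
                         "geometric_fit": geo_fit.fitted}
                    ),
                    emit("sad_octaves.tsv"),
                )

            # ---- Mantel --------------------------------------------------
            if "mantel" in config.stages and meta is not None:
                stage = "mantel"
                env = env_distance(meta)
                geo = geo_distance(meta, mode=config.mantel.get("geo_mode", "haversine_km"))
                targets = dict(beta_mats)
                if bnti_res is not None:
                    targets["bnti"] = bnti_res.bnti
                results = {}
                for name, mat in sorted(targets.items()):
                    if not np.isfinite(mat.condensed()).all():
                        notes.append(f"mantel: skipped {name} (non-finite entries)")
                        continue
                    for dist_name, dist in (("env", env), ("geo", geo)):
                        res = mantel(
                            mat, dist,
                            method=config.mantel.get("method", "pearson"),
                            n_perm=config.mantel.get("n_perm", 9999),
                            seed=substream_seed(config.seed, f"mantel:{name}:{dist_name}"),
                        )
                        results[f"{name}_vs_{dist_name}"] = {
                            "r": res.r, "p": res.p, "n_perm": res.n_perm,
                            "method": res.method,
                        }
                _write_json(results, emit("mantel.json"))

        notes.extend(str(w.message) for w in caught)

    except StageError:
        raise
    except Exception as exc:  # halt with the stage name and partial manifest
        raise StageError(stage, manifest, exc) from exc

    manifest.append("report.json")
    report = RunReport(
        out_dir=str(out),
        manifest=manifest,
        warnings=notes,
        config_hash=config.config_hash(),
    )
    _write_json(report.to_dict(), out / "report.json")
    return report
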