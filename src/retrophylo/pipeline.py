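"""End-to-end orchestration: retrotransposon analysis and exon census runs.

A run is driven by a :class:`RunConfig` (loadable from a TOML file); every
stochastic stage takes an explicit seed and a completed run emits a single
JSON-serializable report with a provenance block (config hash, seeds,
package version) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .marker_matrix import (
    OUTGROUP,
    OrderMap,
    PresenceAbsenceMatrix,
    census_patterns,
    collapse_to_orders,
    export_splits_nexus,
    read_matrix,
)
from .dollo import BootstrapConfig, bootstrap_support, search_best_tree
from .coalescent import (
    LocalPPConfig,
    in_anomaly_zone,
    species_tree_from_markers,
)
from .introgression import fit_and_lrt, quartet_asymmetry_test
from .simulator import (
    SimulationScenario,
    scenario_order_map,
    simulate_markers,
)

__all__ = ["ConfigError", "StageError", "RunConfig", "run_retro_analysis", "run_exon_census"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``matrix_path`` (+ ``order_map``) or ``scenario`` must be given
    for the retrotransposon pipeline; ``exon_dir`` for the exon census.
    """

    matrix_path: str | None = None
    matrix_format: str = "tsv"
    order_map: dict[str, str] = field(default_factory=dict)
    scenario: SimulationScenario | None = None
    outgroup: str | None = OUTGROUP
    seed: int = 0
    bootstrap_replicates: int = 1000
    pp_lam: float = 0.5
    run_lrt: bool = False
    lrt_n_mc: int = 20000
    out_dir: str | None = None
    exon_dir: str | None = None
    species_tree_path: str | None = None
    min_exon_len: int = 500
    collapse_threshold: float = 0.01

    def provenance(self) -> dict:
        blob = {
            k: v
            for k, v in asdict(self).items()
            if not isinstance(v, SimulationScenario)
        }
        if self.scenario is not None:
            blob["scenario"] = asdict(self.scenario)
        digest = hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {
            "config_hash": digest,
            "seed": self.seed,
            "version": __version__,
        }

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        try:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        except FileNotFoundError:
            raise ConfigError(f"config file {path!r} not found") from None
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"config parse error: {exc}") from exc
        scenario = None
        if "scenario" in data:
            scenario = SimulationScenario(**data.pop("scenario"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(scenario=scenario, **data)


def _stage(name: str, fn, report: dict, *args, **kwargs):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(name, exc) from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
    return result


def run_retro_analysis(config: RunConfig) -> dict:
    """Census -> splits export -> Dollo search + bootstrap -> coalescent
    annotation -> anomaly-zone check -> quartet-asymmetry test (and the
    introgression LRT when enabled).  Returns the JSON-ready report."""
    if config.matrix_path is None and config.scenario is None:
        raise ConfigError("either matrix_path or scenario must be configured")
    report: dict = {"provenance": config.provenance()}

    if config.scenario is not None:
        matrix, truth = _stage(
            "simulate", simulate_markers, report, config.scenario
        )
        order_map = scenario_order_map(config.scenario)
        report["simulation"] = {
            "true_topology": truth.topology_newick,
            "true_x": truth.x,
            "true_y": truth.y,
            "n_markers": matrix.n_markers,
            "mode": truth.mode,
            "insertion_rate": truth.insertion_rate,
        }
    else:
        if not Path(config.matrix_path).exists():
            raise ConfigError(f"matrix path {config.matrix_path!r} not found")
        if not config.order_map:
            raise ConfigError("order_map is required with matrix_path")
        matrix = _stage(
            "read_matrix", read_matrix, report,
            config.matrix_path, config.matrix_format,
        )
        order_map = OrderMap(dict(config.order_map))

    collapsed = _stage(
        "collapse", collapse_to_orders, report, matrix, order_map, "strict"
    )
    census = _stage("census", census_patterns, report, collapsed)
    report["census"] = {
        "informative": census.informative,
        "uninformative": census.uninformative,
        "conflicted": census.conflicted,
        "total": census.total,
        "classes": {
            "+".join(sorted(c)): n for c, n in census.counts.items() if n > 0
        },
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        _stage(
            "splits_export", export_splits_nexus, report,
            census, [t for t in collapsed.taxa if t != OUTGROUP],
            str(out_dir / "splits.nex"),
        )

    # Dollo parsimony on the order-level matrix
    order_matrix = collapsed
    optima, steps = _stage(
        "dollo_search", search_best_tree, report,
        order_matrix, None, config.outgroup,
    )
    support = _stage(
        "dollo_bootstrap", bootstrap_support, report,
        order_matrix, None, config.outgroup,
        BootstrapConfig(config.bootstrap_replicates, config.seed),
    )
    report["dollo"] = {
        "best_trees": [t.newick() for t in optima],
        "steps": steps,
        "bootstrap": {"+".join(sorted(c)): v for c, v in support.items()},
    }

    # coalescent annotation and anomaly-zone evaluation
    sptree, ties = _stage(
        "coalescent", species_tree_from_markers, report,
        order_matrix, config.outgroup, "quadruples",
        LocalPPConfig(lam=config.pp_lam),
    )
    branches = {
        "+".join(sorted(clade)): {
            "n1": ann.support.n1,
            "n2": ann.support.n2,
            "n3": ann.support.n3,
            "t_cu": ann.length_cu,
            "pp": ann.pp[0],
            "saturated": ann.saturated,
        }
        for clade, ann in sptree.branches.items()
    }
    report["coalescent"] = {
        "tree": sptree.newick(),
        "ties": [t.newick() for t in ties],
        "branches": branches,
    }
    # the two consecutive focal branches: x above (Per,Cet,Fer), y above (Cet,Fer)
    fu = frozenset({"Perissodactyla", "Cetartiodactyla", "Ferae"})
    cf = frozenset({"Cetartiodactyla", "Ferae"})
    if fu in sptree.branches and cf in sptree.branches:
        x_hat = sptree.branches[fu].length_cu
        y_hat = sptree.branches[cf].length_cu
        if x_hat > 0 and y_hat > 0:
            az = _stage("anomaly_zone", in_anomaly_zone, report, x_hat, y_hat)
            report["anomaly_zone"] = {
                "x_hat": az.x, "y_hat": az.y,
                "boundary_a_x": az.a_x, "in_zone": az.in_zone,
            }
        else:
            report["anomaly_zone"] = {
                "x_hat": x_hat, "y_hat": y_hat,
                "boundary_a_x": None, "in_zone": None,
            }

    # quartet-asymmetry test on the discordant classes of the deepest
    # contested branch (Cetartioferae): discordant pairs Cet+Per and Fer+Per
    n2 = census.count("Cetartiodactyla", "Perissodactyla")
    n3 = census.count("Ferae", "Perissodactyla")
    if n2 + n3 > 0:
        asym = _stage("asymmetry", quartet_asymmetry_test, report, n2, n3)
        report["quartet_asymmetry"] = {
            "n2": asym.n2, "n3": asym.n3,
            "p_value": asym.p_value, "chi2": asym.chi2,
        }

    if config.run_lrt:
        counts = _scrotiferan_class_counts(census)
        lrt = _stage(
            "introgression_lrt", fit_and_lrt, report,
            counts, config.lrt_n_mc, config.seed,
        )
        report["introgression_lrt"] = {
            "statistic": lrt.statistic,
            "p_value": lrt.p_value,
            "p_value_chi2": lrt.p_value_chi2,
            "gamma_hat": lrt.gamma_hat,
            "x_hat": lrt.x_alt,
            "y_hat": lrt.y_alt,
            "converged": lrt.converged,
        }

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _scrotiferan_class_counts(census) -> np.ndarray:
    """Map the census onto the ten scrotiferan 4-lineage classes in the
    generic order (A=Cetartiodactyla, B=Ferae, C=Perissodactyla,
    D=Chiroptera)."""
    name = {"A": "Cetartiodactyla", "B": "Ferae", "C": "Perissodactyla",
            "D": "Chiroptera"}
    from .introgression import CLASS_LABELS

    counts = []
    for cls in CLASS_LABELS:
        orders = frozenset(name[ch] for ch in cls)
        counts.append(census.counts.get(orders, 0))
    return np.asarray(counts, dtype=float)


def run_exon_census(config: RunConfig) -> dict:
    """Coverage filter -> trim -> concatenate -> PI census -> length stats
    -> optional short-branch collapse and RF table against a species tree."""
    from .exon import (
        CoverageRule,
        ExonConfig,
        collapse_short_branches,
        concatenate,
        length_stats,
        pi_site_count,
        read_exon_fasta,
        rf_distance,
    )

    if not config.exon_dir:
        raise ConfigError("exon_dir must be configured")
    exon_dir = Path(config.exon_dir)
    if not exon_dir.is_dir():
        raise ConfigError(f"exon directory {config.exon_dir!r} not found")
    paths = sorted(exon_dir.glob("*.fa")) + sorted(exon_dir.glob("*.fasta"))
    if not paths:
        raise ConfigError(f"no FASTA files in {config.exon_dir!r}")
    report: dict = {"provenance": config.provenance()}
    exons = [_stage("read_exons", read_exon_fasta, report, p) for p in paths]
    nt, partitions, aa = _stage("concatenate", concatenate, report, exons)
    cfg = ExonConfig(config.min_exon_len, config.collapse_threshold)
    report["exons"] = {
        "n_exons": len(exons),
        "nt_columns": len(next(iter(nt.values()))),
        "aa_columns": len(next(iter(aa.values()))),
        "partitions": [
            {"name": n, "start": s, "end": e} for n, s, e in partitions
        ],
        "pi_sites_nt": _stage("pi_nt", pi_site_count, report, nt, "nt"),
        "pi_sites_aa": _stage("pi_aa", pi_site_count, report, aa, "aa"),
        "length_stats": _stage(
            "length_stats", length_stats, report,
            [e.length for e in exons], cfg.min_exon_len,
        ),
    }
    if config.species_tree_path:
        with open(config.species_tree_path) as fh:
            sp_newick = fh.read()
        gene_tree_dir = exon_dir / "gene_trees"
        rf_rows = []
        if gene_tree_dir.is_dir():
            for gt_path in sorted(gene_tree_dir.glob("*.nwk")):
                with open(gt_path) as fh:
                    gt = fh.read()
                collapsed = collapse_short_branches(gt, cfg.collapse_threshold)
                rf_rows.append(
                    {
                        "gene_tree": gt_path.stem,
                        "rf": rf_distance(gt, sp_newick),
                        "rf_collapsed": rf_distance(
                            collapsed.as_string(schema="newick"), sp_newick
                        ),
                    }
                )
        report["rf"] = rf_rows
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "exon_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
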