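"""End-to-end orchestration: simulate -> network -> cluster -> compare,
plus the expression prefilter, with a flat JSON config and a provenance
record.

Every stage is also runnable on its own file outputs (see
:mod:`plomcon.cli`), so any stage can be swapped for real data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .datatypes import PlomconError
from .expression import fold_change_filter, global_normalize
from .graph import compare_network_grids, extract_dense_clusters, ocg_cluster
from .io import (
    write_clusters_json,
    write_difference_csv,
    write_edge_list,
    write_matrix_csv,
    write_network_graphml,
)
from .model import CovariationModel
from .synthetic import default_study_spec, generate_expression_matrix, generate_timecourse_features

logger = logging.getLogger(__name__)


class StageError(PlomconError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Flat run configuration with per-stage sections."""

    seed: int = 0
    rho_grid: tuple[float, ...] = (0.9, 0.95)
    standardize: bool = True
    penalize_diagonal: bool = True
    block_mode: str = "absolute"
    n_proteins: int = 36
    noise_sd: float = 4.0
    cluster_init: str = "cliques"
    expression_n_genes: int = 1000
    expression_n_per_group: int = 3
    expression_de: tuple[tuple[str, float], ...] = ()
    target_median: float = 25.0
    fold_threshold: float = 1.5
    conditions: tuple[str, str] = ("control", "treated")
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        if any(r <= 0 for r in cfg.rho_grid):
            raise ValueError("rho values must be positive")
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__ if k != "extra"}
        d.update(self.extra)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the feature-level pipeline end to end.

    Simulates two-condition time-course feature tables with a planted
    control-only covariation, fits one network per condition per rho,
    clusters each network, writes the two-condition difference report,
    and runs the expression prefilter — all deterministic given the
    config seed.  Returns the provenance record (also written to
    ``provenance.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def emit(path: Path) -> Path:
        outputs.append(path)
        return path

    # -- simulate ------------------------------------------------------------
    stage = "simulate"
    try:
        spec = default_study_spec(n_proteins=config.n_proteins, noise_sd=config.noise_sd)
        tables = {
            cond: generate_timecourse_features(spec, cond, seed=config.seed)
            for cond in config.conditions
        }
        for cond, table in tables.items():
            table.to_csv(emit(outdir / f"features_{cond}.csv"))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "E_SIMULATE", str(exc)) from exc

    # -- network / cluster ---------------------------------------------------
    stage = "network"
    try:
        nets: dict[str, dict[float, object]] = {}
        for cond, table in tables.items():
            model = CovariationModel(table, standardize=config.standardize)
            results = model.fit_grid(
                config.rho_grid,
                penalize_diagonal=config.penalize_diagonal,
                block_mode=config.block_mode,  # type: ignore[arg-type]
            )
            nets[cond] = {}
            for rho, res in results.items():
                tag = f"{cond}_rho{rho:g}"
                write_matrix_csv(emit(outdir / f"precision_{tag}.csv"),
                                 res.precision, res.adjacency.feature_index)
                write_matrix_csv(emit(outdir / f"partialcorr_{tag}.csv"),
                                 res.partial_corr, res.adjacency.feature_index)
                net = res.network
                write_edge_list(emit(outdir / f"edges_{tag}.csv"), net)
                write_network_graphml(emit(outdir / f"network_{tag}.graphml"), net)
                nets[cond][rho] = net
                if net.graph.number_of_edges() > 0:
                    cs = ocg_cluster(net, init=config.cluster_init)  # type: ignore[arg-type]
                    write_clusters_json(emit(outdir / f"clusters_{tag}.json"), cs)
                    dense = extract_dense_clusters(cs, net)
                    write_clusters_json(emit(outdir / f"clusters_dense_{tag}.json"), dense)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "E_NETWORK", str(exc)) from exc

    # -- compare -------------------------------------------------------------
    stage = "compare"
    try:
        ctrl, trt = config.conditions
        diff = compare_network_grids(nets[ctrl], nets[trt])
        write_difference_csv(emit(outdir / "difference_report.csv"), diff)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "E_COMPARE", str(exc)) from exc

    # -- expression prefilter ------------------------------------------------
    stage = "expression"
    try:
        em, truth = generate_expression_matrix(
            config.expression_n_genes,
            config.expression_n_per_group,
            de_spec=config.expression_de,
            seed=config.seed,
        )
        norm = global_normalize(em, target_median=config.target_median)
        norm.to_frame().to_csv(emit(outdir / "expression_normalized.csv"))
        fc = fold_change_filter(norm, threshold=config.fold_threshold)
        fc.to_frame().to_csv(emit(outdir / "fold_change.csv"))
        (outdir / "genes_up.txt").write_text("\n".join(fc.up) + "\n")
        (outdir / "genes_down.txt").write_text("\n".join(fc.down) + "\n")
        outputs.extend([outdir / "genes_up.txt", outdir / "genes_down.txt"])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, "E_EXPRESSION", str(exc)) from exc

    provenance = {
        "package": "plomcon",
        "version": __version__,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=list))
    logger.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return provenance
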