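"""Full reconstruction pipeline: expression → MI → η^L → ρ^L / M / MZ → AUPRC.

The pipeline writes every intermediate matrix, an evaluation report and
a manifest (config snapshot, per-stage outputs with checksums, timings)
sufficient to re-run the computation identically.  All numeric outputs
are independent of the worker count and tile size: tiles are pure
functions of their index ranges and max/min arithmetic is
order-independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import uuid
from dataclasses import dataclass, field
from pathlib import Path

from .datatypes import RunConfig, ValidationError
from .ensemble import (
    auprc,
    ensemble_score,
    optimize_ensemble,
    stouffer_transform,
)
from .io import (
    read_expression,
    read_groundtruth,
    read_id_list,
    write_config,
    write_scores,
    write_weight_matrix,
)
from .mcp import eta, grn_eta, mcp_score
from .parallel import TileError, parallel_map_tiles  # noqa: F401  (re-export)
from .similarity import mi_matrix

__all__ = ["PipelineError", "PipelineManifest", "run_pipeline", "parallel_map_tiles"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the failing stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause!r}")


@dataclass
class PipelineManifest:
    run_id: str
    config: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    success: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_id": self.run_id,
                "config": self.config,
                "stages": self.stages,
                "outputs": self.outputs,
                "success": self.success,
            },
            indent=2,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    expr_path,
    gt_pos_path,
    gt_neg_path,
    out_dir,
    tf_path=None,
) -> PipelineManifest:
    """Execute the full reconstruction pipeline.

    GCN mode by default; supplying ``tf_path`` (one TF id per line)
    switches to the directed TF–target GRN path model.  Writes, per
    configured length L, ``eta_L.tsv`` and ``R_L.tsv``, then the
    ensemble matrix ``M.tsv``, its Stouffer transform ``MZ.tsv``, an
    ``evaluation.tsv`` report, the config snapshot and
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(
        run_id=uuid.uuid4().hex[:12],
        config={
            "path_lengths": list(config.path_lengths),
            "ensemble_interval": config.ensemble_interval,
            "include_direct_term": config.include_direct_term,
            "mi_significance": config.mi_significance,
            "seed": config.seed,
            "n_workers": config.n_workers,
            "tile_size": config.tile_size,
            "expr_path": str(expr_path),
            "gt_pos_path": str(gt_pos_path),
            "gt_neg_path": str(gt_neg_path),
            "tf_path": str(tf_path) if tf_path else None,
        },
    )

    def stage(name):
        def decorator(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:
                manifest.stages.append(
                    {"name": name, "seconds": time.perf_counter() - t0, "ok": False}
                )
                _write_manifest(manifest, out_dir)
                raise PipelineError(name, exc) from exc
            manifest.stages.append(
                {"name": name, "seconds": time.perf_counter() - t0, "ok": True}
            )
            logger.info("stage %s: done", name)
            return result

        return decorator

    def record(name, path):
        manifest.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    grn = tf_path is not None
    tf_ids = read_id_list(tf_path) if grn else None

    @stage("expression")
    def expr():
        return read_expression(expr_path)

    @stage("groundtruth")
    def gt():
        return read_groundtruth(gt_pos_path, gt_neg_path, directed=grn)

    @stage("similarity")
    def W():
        w = mi_matrix(expr, significance=config.mi_significance, tf_ids=tf_ids)
        path = out_dir / "W.tsv"
        write_weight_matrix(w, path)
        record("W", path)
        return w

    if grn:
        # TF-TF submatrix for the regulatory path model
        col_pos = [W.col_ids.index(t) for t in W.row_ids]
        from .datatypes import WeightMatrix

        W_tt = WeightMatrix.gcn(list(W.row_ids), W.values[:, col_pos])

    @stage("capacities")
    def etas():
        out = {}
        for L in config.path_lengths:
            if grn:
                cap = grn_eta(
                    W_tt, W, L, tile_size=config.tile_size, n_workers=config.n_workers
                )
            else:
                cap = eta(W, L, tile_size=config.tile_size, n_workers=config.n_workers)
            path = out_dir / f"eta_{L}.tsv"
            write_scores(cap, path, format="dense-tsv")
            record(f"eta_{L}", path)
            out[L] = cap
        return out

    @stage("mcp_scores")
    def r_scores():
        out = {}
        for L, cap in etas.items():
            score = mcp_score(W, cap)
            path = out_dir / f"R_{L}.tsv"
            write_scores(score, path, format="dense-tsv")
            record(f"R_{L}", path)
            out[L] = score
        return out

    @stage("ensemble")
    def ensemble_outputs():
        lengths = config.ensemble_lengths
        coeffs, train_pr = optimize_ensemble(
            W, etas, gt, interval=config.ensemble_interval, lengths=lengths
        )
        M = ensemble_score(W, etas, coeffs)
        m_path = out_dir / "M.tsv"
        write_scores(M, m_path, format="dense-tsv")
        record("M", m_path)
        MZ = stouffer_transform(M)
        mz_path = out_dir / "MZ.tsv"
        write_scores(MZ, mz_path, format="dense-tsv")
        record("MZ", mz_path)
        return coeffs, train_pr, M, MZ

    coeffs, train_pr, M, MZ = ensemble_outputs

    @stage("evaluation")
    def evaluation():
        rows = [("network", "auprc")]
        for L, score in r_scores.items():
            rows.append((f"R{L}", f"{auprc(score, gt).auprc:.10g}"))
        rows.append(("M", f"{auprc(M, gt).auprc:.10g}"))
        rows.append(("MZ", f"{auprc(MZ, gt).auprc:.10g}"))
        rows.append(
            ("ensemble_weights", ",".join(f"{w:.3g}" for w in coeffs.weights))
        )
        path = out_dir / "evaluation.tsv"
        path.write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")
        record("evaluation", path)

    config_path = out_dir / "config.yaml"
    write_config(config, config_path)
    record("config", config_path)
    manifest.success = True
    _write_manifest(manifest, out_dir)
    for name, entry in manifest.outputs.items():
        if not Path(entry["path"]).exists():  # pragma: no cover - safety net
            raise PipelineError("manifest", ValidationError(f"missing output {name}"))
    return manifest


def _write_manifest(manifest: PipelineManifest, out_dir: Path) -> None:
    (Path(out_dir) / "manifest.json").write_text(
        manifest.to_json(), encoding="utf-8"
    )
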