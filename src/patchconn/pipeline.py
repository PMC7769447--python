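"""Threshold-sweep orchestration: geometry → graphs → indices → priorities.

``run_sweep`` executes the full analysis for a list of dispersal distance
thresholds and writes a self-describing set of text artifacts: a summary
table (one row per threshold with NL, NC, the area-covering component count
in parentheses, and the IIC numerator), per-threshold importance tables,
component and top-priority GeoJSON layers, and the fraction-profile table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import PatchConnError
from .graph_core import build_threshold_graph, components, components_covering
from .indices import fraction_profile, iic, node_importance
from .io_geometry import PatchLayer, pairwise_edge_distances, read_patch_layer
from .prioritize import top_fraction
from .synthetic import LandscapeConfig, generate_landscape

__all__ = ["SweepReport", "run_sweep"]

log = logging.getLogger("patchconn")


@dataclass
class SweepReport:
    """Per-threshold connectivity summary plus provenance."""

    table: pd.DataFrame  # columns: threshold, nl, nc, nc_covering, iic_num[, iic]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Thresholds ascending, NL non-decreasing, NC non-increasing."""
        t = self.table
        if not t["threshold"].is_monotonic_increasing:
            raise AssertionError("thresholds must be sorted ascending")
        if not t["nl"].is_monotonic_increasing:
            raise AssertionError("NL must be non-decreasing in the threshold")
        if not t["nc"].is_monotonic_decreasing:
            raise AssertionError("NC must be non-increasing in the threshold")

    def to_tsv(self, path: str | Path) -> None:
        """Summary with the covering count in parentheses after NC."""
        t = self.table
        lines = ["threshold_m\tNL\tNC(covering)\tIIC_num_ha2"
                 + ("\tIIC" if "iic" in t.columns else "")]
        for _, row in t.iterrows():
            line = (
                f"{row['threshold']:g}\t{int(row['nl'])}\t"
                f"{int(row['nc'])} ({int(row['nc_covering'])})\t{row['iic_num']:.6g}"
            )
            if "iic" in t.columns:
                line += f"\t{row['iic']:.6g}"
            lines.append(line)
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PatchConnError):
                raise PatchConnError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_sweep(
    patches_source: str | Path | PatchLayer | LandscapeConfig,
    thresholds: list[float],
    p: float = 0.5,
    a_l: float | None = None,
    out_dir: str | Path | None = None,
    top_q: float = 0.2,
) -> SweepReport:
    """Run the connectivity analysis for every dispersal threshold.

    ``patches_source`` may be a GeoJSON path, an in-memory
    :class:`PatchLayer`, or a :class:`LandscapeConfig` (a synthetic landscape
    is generated).  The edge list is computed once at cutoff
    ``max(thresholds)`` and pruned per threshold.  With ``out_dir``, artifact
    files are written; on any failure, partial outputs are removed.
    """
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be non-empty and positive")
    thresholds = sorted(thresholds)
    cutoff = max(thresholds)

    provenance: dict = {
        "version": __version__,
        "cutoff_m": cutoff,
        "thresholds_m": thresholds,
        "coverage_p": p,
        "a_l_ha": a_l,
    }
    with _stage("io_geometry"):
        if isinstance(patches_source, LandscapeConfig):
            layer, _ = generate_landscape(patches_source)
            provenance["source"] = {"synthetic": vars(patches_source).copy()}
            provenance["source"]["synthetic"].pop("_index", None)
        elif isinstance(patches_source, PatchLayer):
            layer = patches_source
            provenance["source"] = "in-memory layer"
        else:
            layer = read_patch_layer(patches_source)
            provenance["source"] = str(patches_source)
        provenance["n_patches"] = len(layer)
        edges = pairwise_edge_distances(layer, cutoff=cutoff)
        areas = layer.area_map()

    rows = []
    importance: dict[float, pd.DataFrame] = {}
    partitions = {}
    for d in thresholds:
        with _stage(f"graph d={d:g}"):
            g = build_threshold_graph(areas, edges, d)
            part = components(g)
            partitions[d] = part
            row = {
                "threshold": d,
                "nl": g.nl,
                "nc": part.nc,
                "nc_covering": components_covering(part, p),
            }
        with _stage(f"indices d={d:g}"):
            res = iic(g, a_l)
            row["iic_num"] = res.iic_num
            if res.iic is not None:
                row["iic"] = res.iic
            if g.n_nodes >= 2:
                importance[d] = node_importance(g, a_l)
            else:
                log.info("single patch: importance skipped at d=%g", d)
        rows.append(row)

    report = SweepReport(pd.DataFrame(rows), provenance)
    report.validate()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            path = out / "summary.tsv"
            report.to_tsv(path)
            written.append(path)
            for d, table in importance.items():
                path = out / f"importance_d{d:g}.tsv"
                table.to_csv(path, sep="\t", index=False, float_format="%.6g")
                written.append(path)
                flags = {
                    pid: {"priority": True} for pid in top_fraction(table, top_q)
                }
                path = out / f"top{int(round(top_q * 100))}_d{d:g}.geojson"
                sel = [i for i, pid in enumerate(layer.ids) if pid in flags]
                PatchLayer(
                    [layer.ids[i] for i in sel],
                    [layer.geometries[i] for i in sel],
                ).to_geojson(path, extra_properties=flags)
                written.append(path)
            for d, part in partitions.items():
                path = out / f"components_d{d:g}.geojson"
                comp_props = {
                    pid: {"component": int(c)} for pid, c in part.labels.items()
                }
                layer.to_geojson(path, extra_properties=comp_props)
                written.append(path)
            if importance:
                path = out / "fraction_profile.tsv"
                fraction_profile(importance).to_csv(
                    path, sep="\t", index=False, float_format="%.6g"
                )
                written.append(path)
            path = out / "provenance.txt"
            path.write_text(
                "\n".join(f"{k}={v}" for k, v in provenance.items()) + "\n",
                encoding="utf-8",
            )
            written.append(path)
        except Exception:
            for f in written:
                f.unlink(missing_ok=True)
            raise

    report.importance = importance  # type: ignore[attr-defined]
    return report
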