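"""Static renderings of the three figure types.

* the multi-track main plot: a clinical group band, a gene-expression bar
  band, and one row per exon/junction feature in which each sample's usage
  value is drawn as a vertical mark of height proportional to y_ij; the
  transcript structure diagram (exon boxes joined by intron lines) sits in
  the left panel;
* per-group isoform expression box plots (Tukey whiskers at 1.5 IQR);
* Kaplan–Meier step plots with censor ticks and a group legend.

Samples are ordered within each clinical group by ascending gene expression
(ties broken by sample id), mirroring the low-to-high column arrangement of
the interactive original.  Every usage cell carries ``data-sample-id``,
``data-feature-id`` and ``data-y`` attributes so rendered values can be
parsed back and checked against the usage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genemodels import GeneModel
from .survival import KMCurve
from .svgdoc import SVGDocument, color_map, fmt, fmt_data
from .usage import GeneExpressionVector, UsageMatrix

DEFAULT_OPTIONS = {
    "cell_width": 4.0,
    "row_height": 24.0,
    "group_band_height": 20.0,
    "expr_band_height": 60.0,
    "left_panel_width": 220.0,
    "transcript_row_height": 18.0,
    "margin": 10.0,
    "gap": 6.0,
}


@dataclass
class PlotSpec:
    """Declarative description of one main multi-track plot."""

    gene: GeneModel
    usage: UsageMatrix
    gene_expr: GeneExpressionVector
    groups: list[tuple[str, list[str]]]
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups or all(len(s) == 0 for _, s in self.groups):
            raise ValueError("groups must contain at least one sample")
        known = set(self.usage.sample_ids)
        seen: set[str] = set()
        for label, sids in self.groups:
            for sid in sids:
                if sid not in known:
                    raise ValueError(f"group {label!r}: sample {sid!r} not in usage matrix")
                if sid in seen:
                    raise ValueError(f"sample {sid!r} appears in more than one group")
                seen.add(sid)
        opts = dict(DEFAULT_OPTIONS)
        opts.update(self.options)
        self.options = opts


def order_samples(
    groups: list[tuple[str, list[str]]], gene_expr: GeneExpressionVector
) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Concatenate groups, each sorted by ascending e_j then sample id.

    Returns the flat ordered sample list and per-group (label, start, end)
    index ranges into it.
    """
    e = dict(zip(gene_expr.sample_ids, gene_expr.values))
    ordered: list[str] = []
    bounds: list[tuple[str, int, int]] = []
    for label, sids in groups:
        start = len(ordered)
        ordered.extend(sorted(sids, key=lambda s: (e[s], s)))
        bounds.append((label, start, len(ordered)))
    return ordered, bounds


def layout_transcripts(
    gene: GeneModel, pixel_width: float
) -> list[dict]:
    """Linear genomic -> pixel geometry for each transcript isoform.

    Per transcript: the intron backbone line endpoints and one (x, width)
    box per exon, all in [0, pixel_width] over the gene span.
    """
    span = gene.span
    scale = pixel_width / span.length

    def px(pos: int) -> float:
        return (pos - span.start) * scale

    rows = []
    for tx in gene.transcripts:
        boxes = [
            {"x": px(e.start), "width": (e.end - e.start) * scale, "exon": e}
            for e in tx.exons
        ]
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "line": (px(tx.span.start), px(tx.span.end)),
                "boxes": boxes,
            }
        )
    return rows


def render_main(spec: PlotSpec) -> SVGDocument:
    """Render the multi-track main plot as a deterministic SVG document."""
    opts = spec.options
    ordered, bounds = order_samples(spec.groups, spec.gene_expr)
    n_feat = len(spec.usage.feature_ids)
    cw = opts["cell_width"]
    rh = opts["row_height"]
    margin = opts["margin"]
    gap = opts["gap"]
    left_w = opts["left_panel_width"]
    grid_w = cw * len(ordered)

    top = margin
    group_y = top
    expr_y = group_y + opts["group_band_height"] + gap
    rows_y = expr_y + opts["expr_band_height"] + gap
    rows_h = n_feat * rh
    tx_h = len(spec.gene.transcripts) * opts["transcript_row_height"]
    height = max(rows_y + rows_h, rows_y + tx_h) + margin
    width = margin + left_w + gap + grid_w + margin
    grid_x = margin + left_w + gap

    doc = SVGDocument(width, height)
    e_by_sample = dict(zip(spec.gene_expr.sample_ids, spec.gene_expr.values))
    colors = color_map([label for label, _, _ in bounds])

    # clinical group band
    g_groups = doc.group("groups")
    for gi, (label, start, end) in enumerate(bounds):
        doc.rect(
            grid_x + start * cw,
            group_y,
            (end - start) * cw,
            opts["group_band_height"],
            parent=g_groups,
            fill=colors[label],
            data_group=label,
            data_n=end - start,
        )
        doc.text(
            grid_x + start * cw + 2,
            group_y + opts["group_band_height"] - 6,
            f"{label} (n={end - start})",
            parent=g_groups,
            font_size="10",
            fill="#ffffff",
        )

    # gene-expression bars, low to high within each group
    g_expr = doc.group("gene-expression")
    e_max = max((e_by_sample[s] for s in ordered), default=0.0)
    for ci, sid in enumerate(ordered):
        h = 0.0 if e_max == 0 else e_by_sample[sid] / e_max * opts["expr_band_height"]
        doc.rect(
            grid_x + ci * cw,
            expr_y + opts["expr_band_height"] - h,
            cw,
            h,
            parent=g_expr,
            fill="#555555",
            data_sample_id=sid,
            data_e=fmt_data(e_by_sample[sid]),
        )

    # usage rows: vertical marks with height proportional to y_ij
    col_of = {sid: i for i, sid in enumerate(ordered)}
    g_rows = doc.group("usage-rows")
    for fi, fid in enumerate(spec.usage.feature_ids):
        row = doc.group(f"feature-{fi}", parent=g_rows, data_feature_id=fid)
        y0 = rows_y + fi * rh
        doc.line(
            grid_x, y0 + rh, grid_x + grid_w, y0 + rh,
            parent=row, stroke="#dddddd", stroke_width="0.5",
        )
        doc.text(
            margin, y0 + rh - 8, fid, parent=row, font_size="8", fill="#333333"
        )
        for sid in ordered:
            j = spec.usage.sample_ids.index(sid)
            yval = float(spec.usage.values[fi, j])
            ci = col_of[sid]
            x = grid_x + ci * cw + cw / 2.0
            doc.line(
                x, y0 + rh, x, y0 + rh - yval * rh,
                parent=row,
                stroke="#1f77b4",
                stroke_width=fmt(cw * 0.8),
                data_sample_id=sid,
                data_feature_id=fid,
                data_y=fmt_data(yval),
            )

    # transcript diagram in the left panel
    g_tx = doc.group("transcripts")
    diagram_w = left_w - 2 * margin
    rows = layout_transcripts(spec.gene, diagram_w)
    for ti, trow in enumerate(rows):
        ty = rows_y + ti * opts["transcript_row_height"]
        mid = ty + opts["transcript_row_height"] / 2.0
        tg = doc.group(
            f"transcript-{ti}", parent=g_tx, data_transcript_id=trow["transcript_id"]
        )
        x1, x2 = trow["line"]
        doc.line(
            margin + x1, mid, margin + x2, mid,
            parent=tg, stroke="#333333", stroke_width="1",
        )
        for box in trow["boxes"]:
            doc.rect(
                margin + box["x"],
                mid - 5,
                box["width"],
                10,
                parent=tg,
                fill="#333333",
            )
    return doc


def render_boxplot(
    groups: list[tuple[str, list[float]]],
    title: str = "",
    width: float = 120.0,
    height: float = 320.0,
) -> SVGDocument:
    """Per-group Tukey box plots of isoform expression.

    Boxes span the quartiles with the median marked; whiskers reach the most
    extreme points within 1.5 IQR of the box; points beyond are drawn as
    dots.  Quartiles use linear interpolation between order statistics.
    """
    margin = 30.0
    n_groups = len(groups)
    doc = SVGDocument(margin * 2 + width * max(n_groups, 1), height)
    all_vals = [v for _, vals in groups for v in vals]
    if not all_vals:
        raise ValueError("no values to plot")
    vmax = max(all_vals)
    vmin = min(all_vals)
    spread = vmax - vmin or 1.0
    plot_h = height - 2 * margin

    def ypix(v: float) -> float:
        return margin + (vmax - v) / spread * plot_h

    colors = color_map([label for label, _ in groups])
    if title:
        doc.text(margin, margin / 2 + 5, title, font_size="12", fill="#000000")
    for gi, (label, vals) in enumerate(groups):
        cx = margin + width * gi + width / 2.0
        g = doc.group(f"box-{gi}", data_group=label, data_n=len(vals))
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        whisk_lo = float(inside.min()) if inside.size else float(med)
        whisk_hi = float(inside.max()) if inside.size else float(med)
        bw = width * 0.5
        doc.line(cx, ypix(whisk_lo), cx, ypix(q1), parent=g, stroke="#000000")
        doc.line(cx, ypix(q3), cx, ypix(whisk_hi), parent=g, stroke="#000000")
        doc.line(cx - bw / 4, ypix(whisk_lo), cx + bw / 4, ypix(whisk_lo), parent=g, stroke="#000000")
        doc.line(cx - bw / 4, ypix(whisk_hi), cx + bw / 4, ypix(whisk_hi), parent=g, stroke="#000000")
        doc.rect(
            cx - bw / 2,
            ypix(q3),
            bw,
            max(ypix(q1) - ypix(q3), 0.0),
            parent=g,
            fill=colors[label],
            stroke="#000000",
            data_q1=fmt_data(q1),
            data_median=fmt_data(med),
            data_q3=fmt_data(q3),
        )
        doc.line(
            cx - bw / 2, ypix(med), cx + bw / 2, ypix(med),
            parent=g, stroke="#000000", stroke_width="2",
            data_median=fmt_data(med),
        )
        for v in sorted(arr[(arr < lo_fence) | (arr > hi_fence)]):
            doc.circle(cx, ypix(float(v)), 2.0, parent=g, fill="#000000", data_value=fmt_data(float(v)))
        doc.text(cx - bw / 2, height - margin / 3, label, parent=g, font_size="10")
    return doc


def render_km(
    curves: list[KMCurve],
    width: float = 420.0,
    height: float = 320.0,
    cutoff: float | None = None,
) -> SVGDocument:
    """Kaplan–Meier step plot: one path per group, censor ticks, legend."""
    margin = 40.0
    doc = SVGDocument(width, height)
    plot_w = width - 2 * margin
    plot_h = height - 2 * margin
    tmax = max(
        [t for c in curves for t in c.times]
        + [t for c in curves for t in c.censor_times]
        + [1.0]
    )

    def xpix(t: float) -> float:
        return margin + t / tmax * plot_w

    def ypix(s: float) -> float:
        return margin + (1.0 - s) * plot_h

    axes = doc.group("axes")
    doc.line(margin, margin, margin, margin + plot_h, parent=axes, stroke="#000000")
    doc.line(margin, margin + plot_h, margin + plot_w, margin + plot_h, parent=axes, stroke="#000000")
    colors = color_map([c.group_label for c in curves])
    for ci, curve in enumerate(curves):
        g = doc.group(
            f"km-{ci}",
            data_group=curve.group_label,
            data_n=curve.n,
            data_times=",".join(fmt_data(t) for t in curve.times),
            data_survival=",".join(fmt_data(s) for s in curve.survival),
            data_at_risk=",".join(str(r) for r in curve.at_risk),
        )
        color = colors[curve.group_label]
        d = f"M {fmt(xpix(0))} {fmt(ypix(1.0))}"
        s_prev = 1.0
        for t, s in zip(curve.times, curve.survival):
            d += f" L {fmt(xpix(t))} {fmt(ypix(s_prev))}"
            d += f" L {fmt(xpix(t))} {fmt(ypix(s))}"
            s_prev = s
        tail = max(curve.censor_times + curve.times, default=0.0)
        if tail > (curve.times[-1] if curve.times else 0.0):
            d += f" L {fmt(xpix(tail))} {fmt(ypix(s_prev))}"
        doc.path(d, parent=g, fill="none", stroke=color, stroke_width="1.5")
        # censor ticks at the survival level current at the censoring time
        for t in curve.censor_times:
            s_here = 1.0
            for et, es in zip(curve.times, curve.survival):
                if et <= t:
                    s_here = es
                else:
                    break
            doc.line(
                xpix(t), ypix(s_here) - 4, xpix(t), ypix(s_here) + 4,
                parent=g, stroke=color, stroke_width="1",
            )
        label = f"{curve.group_label} (n={curve.n})"
        doc.text(
            margin + plot_w - 150,
            margin + 14 * (ci + 1),
            label,
            parent=g,
            font_size="10",
            fill=color,
        )
    if cutoff is not None:
        doc.text(
            margin + plot_w - 150,
            margin + 14 * (len(curves) + 1),
            f"cutoff = {cutoff:.3f}",
            font_size="10",
            fill="#000000",
        )
    return doc
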