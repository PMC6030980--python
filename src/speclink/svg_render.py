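"""Deterministic SVG 1.1 export of the three coordinated views.

The three views mirror a cross-link spectrum viewer's layout: the annotated
spectrum (peaks colored per peptide, neutral losses lighter, labels above
peaks), the peptide fragmentation key (residue rows with cleavage ticks and
a cross-link connector), and the QC scatter of match error against
intensity or m/z.

Rendering is a pure function of (annotation, style): the same input always
produces byte-identical output.  Peaks in the spectrum view are the only
``<line>`` elements (axes and leader lines are ``<path>``), so element
counts directly reflect peak counts.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import AnnotatedSpectrum, QcPoint

__all__ = ["RenderStyle", "fragkey_svg", "qc_svg", "spectrum_svg"]

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass(frozen=True)
class RenderStyle:
    """Colors and geometry of the exported views.

    The default palette differentiates the two cross-linked peptides as
    red (alpha) and blue (beta); neutral-loss fragments are drawn in a
    color lightened by ``loss_lightening`` (0 = unchanged, 1 = white).
    """

    color_alpha: str = "#d6341f"
    color_beta: str = "#1f77d6"
    unmatched_color: str = "#aaaaaa"
    highlight_color: str = "#ffd400"
    loss_lightening: float = 0.5
    show_loss_labels: bool = True
    width: int = 800
    height: int = 400

    def __post_init__(self) -> None:
        for color in (self.color_alpha, self.color_beta, self.unmatched_color,
                      self.highlight_color):
            if not (color.startswith("#") and len(color) in (4, 7)):
                raise ValueError(f"invalid hex color {color!r}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("render dimensions must be positive")
        if not 0.0 <= self.loss_lightening <= 1.0:
            raise ValueError("loss_lightening must be in [0, 1]")

    def peptide_color(self, peptide_id: str, is_loss: bool = False) -> str:
        base = self.color_alpha if peptide_id == "alpha" else self.color_beta
        return lighten(base, self.loss_lightening) if is_loss else base


def lighten(hex_color: str, factor: float) -> str:
    """Mix a ``#rrggbb`` color toward white by ``factor``."""
    h = hex_color.lstrip("#")
    if len(h) == 3:
        h = "".join(c * 2 for c in h)
    rgb = [int(h[i : i + 2], 16) for i in (0, 2, 4)]
    rgb = [round(c + (255 - c) * factor) for c in rgb]
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _svg_root(width: int, height: int) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )


def _to_text(root: ET.Element) -> str:
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode"
    )


def _axes(parent: ET.Element, x0: float, y0: float, x1: float, y1: float) -> None:
    # y0 = bottom, y1 = top; drawn as a path so <line> stays peak-only
    ET.SubElement(
        parent,
        "path",
        {
            "class": "axes",
            "d": f"M {_fmt(x0)} {_fmt(y1)} L {_fmt(x0)} {_fmt(y0)} L {_fmt(x1)} {_fmt(y0)}",
            "stroke": "#000000",
            "fill": "none",
        },
    )


def _axis_label(parent: ET.Element, x: float, y: float, text: str, cls: str,
                rotate: bool = False) -> None:
    attrs = {"class": cls, "x": _fmt(x), "y": _fmt(y), "font-size": "12",
             "text-anchor": "middle"}
    if rotate:
        attrs["transform"] = f"rotate(-90 {_fmt(x)} {_fmt(y)})"
    ET.SubElement(parent, "text", attrs).text = text


MARGIN = 45.0


# --------------------------------------------------------------------------
# Annotated spectrum
# --------------------------------------------------------------------------


def spectrum_svg(annotated: AnnotatedSpectrum, style: RenderStyle = RenderStyle()) -> str:
    """The annotated mass spectrum as SVG text.

    One vertical ``<line>`` per peak: unmatched peaks neutral gray, matched
    peaks colored by peptide (losses lighter).  Fragment labels sit above
    their peaks with greedy de-overlap (dashed leader lines when displaced);
    ``style.show_loss_labels`` False suppresses neutral-loss labels.
    """
    spec = annotated.spectrum
    root = _svg_root(style.width, style.height)
    x0, y0 = MARGIN, style.height - MARGIN
    x1, y1 = style.width - 15.0, 20.0
    _axes(root, x0, y0, x1, y1)
    _axis_label(root, (x0 + x1) / 2, style.height - 8, "m/z", "x-label")
    _axis_label(root, 14, (y0 + y1) / 2, "relative intensity", "y-label", rotate=True)

    n = len(spec)
    if n:
        mz_lo = float(spec.mz[0])
        mz_hi = float(spec.mz[-1])
        span = (mz_hi - mz_lo) or 1.0
        mz_lo -= 0.02 * span
        mz_hi += 0.02 * span
        span = mz_hi - mz_lo
        imax = float(max(spec.intensity.max(), 1e-12))

        def sx(mz: float) -> float:
            return x0 + (mz - mz_lo) / span * (x1 - x0)

        def sy(inten: float) -> float:
            return y0 - inten / imax * (y0 - y1)

        # best (monoisotopic, smallest |error|) match per peak for styling
        best: dict[int, object] = {}
        for m in annotated.monoisotopic_matches:
            cur = best.get(m.peak_index)
            if cur is None or abs(m.error_da) < abs(cur.error_da):  # type: ignore[attr-defined]
                best[m.peak_index] = m
        matched_isotopes = {
            m.peak_index for m in annotated.matches if m.isotope_peak > 0
        }

        labels: list[tuple[float, float, str, str]] = []
        for k in range(n):
            px = sx(float(spec.mz[k]))
            py = sy(float(spec.intensity[k]))
            m = best.get(k)
            if m is not None:
                frag = m.fragment  # type: ignore[attr-defined]
                is_loss = frag.loss is not None
                color = style.peptide_color(frag.peptide_id, is_loss)
                cls = f"peak matched {frag.peptide_id}" + (" loss" if is_loss else "")
                if not is_loss or style.show_loss_labels:
                    labels.append((px, py, frag.label, color))
            elif k in matched_isotopes:
                color = style.unmatched_color
                cls = "peak isotope"
            else:
                color = style.unmatched_color
                cls = "peak unmatched"
            ET.SubElement(
                root,
                "line",
                {
                    "class": cls,
                    "x1": _fmt(px),
                    "y1": _fmt(y0),
                    "x2": _fmt(px),
                    "y2": _fmt(py),
                    "stroke": color,
                    "stroke-width": "1.5",
                },
            )

        # greedy label de-overlap: left-to-right, stack labels that would
        # collide upward and connect them with dashed leaders
        labels.sort(key=lambda t: (t[0], t[2]))
        min_dx = 22.0
        last_x = -1e9
        last_y = y1
        for px, py, text, color in labels:
            ly = py - 6
            if px - last_x < min_dx:
                ly = min(ly, last_y - 12)
            if ly < y1:
                ly = y1
            if ly != py - 6:
                ET.SubElement(
                    root,
                    "path",
                    {
                        "class": "leader",
                        "d": f"M {_fmt(px)} {_fmt(py)} L {_fmt(px)} {_fmt(ly + 2)}",
                        "stroke": color,
                        "stroke-dasharray": "2,2",
                        "fill": "none",
                    },
                )
            ET.SubElement(
                root,
                "text",
                {
                    "class": "frag-label",
                    "x": _fmt(px),
                    "y": _fmt(ly),
                    "font-size": "10",
                    "fill": color,
                    "text-anchor": "middle",
                },
            ).text = text
            last_x, last_y = px, ly
    return _to_text(root)


# --------------------------------------------------------------------------
# Fragmentation key
# --------------------------------------------------------------------------


def fragkey_svg(annotated: AnnotatedSpectrum, style: RenderStyle = RenderStyle()) -> str:
    """The peptide fragmentation key as SVG text.

    One residue row per peptide in one-letter code; matched cleavage sites
    get tick marks — prefix series (b/c) above the row, suffix series (y/z)
    below.  For cross-linked PSMs the two linked residues are joined by a
    connector line.
    """
    psm = annotated.psm
    step = 22.0
    row_y = [60.0, 130.0]
    root = _svg_root(style.width, max(180, int(style.height / 2)))

    matched_cleavages: dict[tuple[str, str, int], None] = {}
    for m in annotated.monoisotopic_matches:
        f = m.fragment
        if f.series in ("b", "c"):
            matched_cleavages[(f.peptide_id, "prefix", f.index)] = None
        elif f.series in ("y", "z"):
            pep = psm.peptides[0 if f.peptide_id == "alpha" else 1]
            matched_cleavages[(f.peptide_id, "suffix", len(pep) - f.index)] = None

    for p_idx, peptide in enumerate(psm.peptides):
        pid = "alpha" if p_idx == 0 else "beta"
        y = row_y[p_idx]
        color = style.peptide_color(pid)
        for i, residue in enumerate(peptide.sequence, start=1):
            x = MARGIN + (i - 1) * step
            ET.SubElement(
                root,
                "text",
                {
                    "class": f"residue {pid}",
                    "x": _fmt(x),
                    "y": _fmt(y),
                    "font-size": "16",
                    "font-family": "monospace",
                    "fill": color,
                    "text-anchor": "middle",
                },
            ).text = residue
            mods_here = [mod.name for pos, mod in peptide.mods if pos == i]
            if mods_here:
                ET.SubElement(
                    root,
                    "text",
                    {
                        "class": f"mod-label {pid}",
                        "x": _fmt(x),
                        "y": _fmt(y + (14 if p_idx else -24)),
                        "font-size": "9",
                        "fill": color,
                        "text-anchor": "middle",
                    },
                ).text = ",".join(mods_here)
        # cleavage ticks between residue i and i+1
        for i in range(1, len(peptide)):
            x = MARGIN + (i - 0.5) * step
            if (pid, "prefix", i) in matched_cleavages:
                ET.SubElement(
                    root,
                    "line",
                    {
                        "class": f"tick prefix {pid}",
                        "x1": _fmt(x),
                        "y1": _fmt(y - 14),
                        "x2": _fmt(x + 5),
                        "y2": _fmt(y - 6),
                        "stroke": color,
                        "stroke-width": "1.5",
                    },
                )
            if (pid, "suffix", i) in matched_cleavages:
                ET.SubElement(
                    root,
                    "line",
                    {
                        "class": f"tick suffix {pid}",
                        "x1": _fmt(x - 5),
                        "y1": _fmt(y + 4),
                        "x2": _fmt(x),
                        "y2": _fmt(y - 4),
                        "stroke": color,
                        "stroke-width": "1.5",
                    },
                )

    if psm.is_crosslinked:
        xa = MARGIN + (psm.link_positions[0] - 1) * step
        xb = MARGIN + (psm.link_positions[1] - 1) * step
        ET.SubElement(
            root,
            "line",
            {
                "class": "crosslink-connector",
                "x1": _fmt(xa),
                "y1": _fmt(row_y[0] + 6),
                "x2": _fmt(xb),
                "y2": _fmt(row_y[1] - 14),
                "stroke": "#333333",
                "stroke-width": "2",
            },
        )
    return _to_text(root)


# --------------------------------------------------------------------------
# QC error plots
# --------------------------------------------------------------------------


def qc_svg(
    points: Sequence[QcPoint],
    axis: str = "intensity",
    style: RenderStyle = RenderStyle(),
    absolute: bool = False,
) -> str:
    """Match-error scatter (error in ppm over intensity or m/z) as SVG text.

    One ``<circle>`` per point, colored per peptide with neutral-loss points
    lighter.  The y range is symmetric around zero for signed errors and
    starts at zero in absolute mode.
    """
    if axis not in ("intensity", "mz"):
        raise ValueError(f"axis must be 'intensity' or 'mz', got {axis!r}")
    root = _svg_root(style.width, style.height)
    x0, y0 = MARGIN, style.height - MARGIN
    x1, y1 = style.width - 15.0, 20.0
    _axes(root, x0, y0, x1, y1)
    _axis_label(
        root, (x0 + x1) / 2, style.height - 8,
        "intensity" if axis == "intensity" else "m/z", "x-label",
    )
    _axis_label(
        root, 14, (y0 + y1) / 2,
        "|error| (ppm)" if absolute else "error (ppm)", "y-label", rotate=True,
    )
    if points:
        xs = [p.x for p in points]
        errs = [p.error_ppm for p in points]
        x_lo, x_hi = min(xs), max(xs)
        span = (x_hi - x_lo) or 1.0
        x_lo -= 0.05 * span
        x_hi += 0.05 * span
        span = x_hi - x_lo
        if absolute:
            e_lo, e_hi = 0.0, max(max(errs), 1e-9) * 1.1
        else:
            e_max = max(max(abs(e) for e in errs), 1e-9) * 1.1
            e_lo, e_hi = -e_max, e_max

        def sx(v: float) -> float:
            return x0 + (v - x_lo) / span * (x1 - x0)

        def sy(e: float) -> float:
            return y0 - (e - e_lo) / (e_hi - e_lo) * (y0 - y1)

        if not absolute:
            zero_y = sy(0.0)
            ET.SubElement(
                root,
                "path",
                {
                    "class": "zero-line",
                    "d": f"M {_fmt(x0)} {_fmt(zero_y)} L {_fmt(x1)} {_fmt(zero_y)}",
                    "stroke": "#cccccc",
                    "stroke-dasharray": "4,3",
                    "fill": "none",
                },
            )
        for p in points:
            cls = f"qc-point {p.peptide_id}" + (" loss" if p.is_loss else "")
            ET.SubElement(
                root,
                "circle",
                {
                    "class": cls,
                    "cx": _fmt(sx(p.x)),
                    "cy": _fmt(sy(p.error_ppm)),
                    "r": "3",
                    "fill": style.peptide_color(p.peptide_id, p.is_loss),
                },
            )
    return _to_text(root)
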