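"""Render enrichment results on a schematic eukaryotic cell.

The geometry is data, not code: each view ships as an editable SVG template
in ``gocellmap/data``.  Drawable regions are SVG shapes carrying
``class="compartment-region"`` and an ``id`` equal to the compartment name
with spaces replaced by underscores (XML ids cannot contain spaces); text
elements with ``class="compartment-label"`` are the optional labels.
Rendering recolours the regions: compartments significant at the FDR
threshold are filled from a sequential colour scale over -log10(FDR),
everything else is filled white.  Output is deterministic — no timestamps,
fixed element order — so identical inputs give byte-identical documents.
"""

from __future__ import annotations

import copy
import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import matplotlib
import pandas as pd
from lxml import etree
from matplotlib.colors import to_hex

__all__ = [
    "StyleOptions",
    "CellSchematic",
    "load_schematic",
    "render_schematic",
    "rasterize",
    "export_results",
]

SVG_NS = "http://www.w3.org/2000/svg"
REGION_CLASS = "compartment-region"
LABEL_CLASS = "compartment-label"
WHITE = "#ffffff"

#: FDR values of exactly zero (double-precision underflow in extreme
#: enrichments) are floored here before taking log10 for the colour map.
FDR_FLOOR = 1e-300


@dataclass
class StyleOptions:
    """User-tunable rendering style.

    significance_threshold is the FDR cutoff below which a compartment gets
    a colour at all; colour endpoints are expressed on -log10(FDR), with
    ``vmin`` defaulting to -log10(threshold) (just-significant -> lightest)
    and ``vmax`` the saturation point.
    """

    significance_threshold: float = 0.05
    colormap: str = "Reds"
    vmin: float | None = None
    vmax: float = 10.0
    text_size: float = 12.0
    show_labels: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise ValueError("significance threshold must lie in (0, 1)")
        vmin = self.effective_vmin
        if not (math.isfinite(vmin) and math.isfinite(self.vmax) and vmin < self.vmax):
            raise ValueError("colour-scale endpoints must be finite with vmin < vmax")

    @property
    def effective_vmin(self) -> float:
        return -math.log10(self.significance_threshold) if self.vmin is None else self.vmin

    def fill_for(self, fdr: float) -> str:
        if not (fdr < self.significance_threshold):
            return WHITE
        value = -math.log10(max(fdr, FDR_FLOOR))
        span = self.vmax - self.effective_vmin
        x = min(max((value - self.effective_vmin) / span, 0.0), 1.0)
        cmap = matplotlib.colormaps[self.colormap]
        # keep just-significant fills visibly non-white
        return to_hex(cmap(0.15 + 0.85 * x))


@dataclass
class CellSchematic:
    """A parsed schematic: the SVG tree plus its named drawable regions."""

    view: str
    tree: etree._ElementTree
    regions: dict[str, etree._Element] = field(init=False)

    def __post_init__(self) -> None:
        root = self.tree.getroot()
        regions: dict[str, etree._Element] = {}
        for el in root.iter():
            if el.get("class") == REGION_CLASS:
                region_id = el.get("id")
                if not region_id:
                    raise ValueError("compartment region without id in schematic")
                name = region_id.replace("_", " ")
                if name in regions:
                    raise ValueError(f"duplicate region for compartment {name!r}")
                regions[name] = el
        if not regions:
            raise ValueError("schematic defines no compartment regions")
        self.regions = regions

    @property
    def compartments(self) -> list[str]:
        return list(self.regions)


def load_schematic(view: str = "standard", source=None) -> CellSchematic:
    """Load a shipped view template, or a user SVG following the same conventions."""
    if source is None:
        name = f"schematic_{view}.svg"
        ref = resources.files("gocellmap.data").joinpath(name)
        try:
            data = ref.read_bytes()
        except FileNotFoundError as exc:
            raise ValueError(f"no shipped schematic for view {view!r}") from exc
    else:
        data = Path(source).read_bytes()
    tree = etree.ElementTree(etree.fromstring(data))
    return CellSchematic(view=view, tree=tree)


def render_schematic(
    table: pd.DataFrame, schematic: CellSchematic, style: StyleOptions | None = None
) -> bytes:
    """Colour the schematic's regions from an enrichment table; returns SVG bytes.

    Compartments present in the schematic but missing from the table are
    rendered white (non-enriched) with a warning; table rows naming unknown
    compartments are warned about and ignored.
    """
    style = style or StyleOptions()
    table_view = table.attrs.get("view")
    if table_view is not None and table_view != schematic.view:
        raise ValueError(
            f"table was computed for view {table_view!r} but schematic is {schematic.view!r}"
        )
    fdr_by_name = dict(zip(table["compartment"], table["fdr"]))
    unknown = set(fdr_by_name) - set(schematic.regions)
    if unknown:
        warnings.warn(
            f"table rows for compartments absent from the schematic ignored: {sorted(unknown)}",
            stacklevel=2,
        )
    tree = copy.deepcopy(schematic.tree)
    root = tree.getroot()
    regions = {
        el.get("id").replace("_", " "): el
        for el in root.iter()
        if el.get("class") == REGION_CLASS
    }
    for name, el in regions.items():
        if name in fdr_by_name:
            el.set("fill", style.fill_for(float(fdr_by_name[name])))
        else:
            warnings.warn(
                f"no enrichment row for compartment {name!r}; rendered as non-enriched",
                stacklevel=2,
            )
            el.set("fill", WHITE)
    for el in list(root.iter()):
        if el.get("class") == LABEL_CLASS:
            if style.show_labels:
                el.set("font-size", f"{style.text_size:g}")
            else:
                el.getparent().remove(el)
    return etree.tostring(tree, xml_declaration=True, encoding="UTF-8")


def _float(el, attr, default=0.0):
    value = el.get(attr)
    return float(value) if value is not None else default


def rasterize(svg_bytes: bytes, dpi: int = 100) -> bytes:
    """Minimal PNG rasterization of a rendered schematic.

    Understands the primitive shapes the shipped templates use (rect,
    circle, ellipse, text) and draws them with matplotlib; arbitrary SVG is
    out of scope.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt

    root = etree.fromstring(svg_bytes)
    width = float(root.get("width", 800))
    height = float(root.get("height", 600))
    fig, ax = plt.subplots(figsize=(width / dpi, height / dpi), dpi=dpi)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)  # SVG y grows downward
    ax.axis("off")

    def styles(el):
        return dict(
            facecolor=el.get("fill", "none"),
            edgecolor=el.get("stroke", "none"),
            linewidth=float(el.get("stroke-width", 1.0)),
        )

    for el in root.iter():
        if not isinstance(el.tag, str):
            continue  # comments, processing instructions
        tag = etree.QName(el).localname
        if tag == "rect":
            ax.add_patch(
                mpatches.FancyBboxPatch(
                    (_float(el, "x"), _float(el, "y")),
                    _float(el, "width"),
                    _float(el, "height"),
                    boxstyle=f"round,pad=0,rounding_size={_float(el, 'rx')}",
                    mutation_aspect=1,
                    **styles(el),
                )
            )
        elif tag == "circle":
            ax.add_patch(
                mpatches.Circle(
                    (_float(el, "cx"), _float(el, "cy")), _float(el, "r"), **styles(el)
                )
            )
        elif tag == "ellipse":
            ax.add_patch(
                mpatches.Ellipse(
                    (_float(el, "cx"), _float(el, "cy")),
                    2 * _float(el, "rx"),
                    2 * _float(el, "ry"),
                    **styles(el),
                )
            )
        elif tag == "text" and el.text:
            ax.text(
                _float(el, "x"),
                _float(el, "y"),
                el.text,
                fontsize=float(el.get("font-size", 12)),
                color=el.get("fill", "#000000"),
                ha={"middle": "center", "end": "right"}.get(el.get("text-anchor"), "left"),
            )
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=dpi)
    plt.close(fig)
    return buf.getvalue()


def export_results(
    table: pd.DataFrame,
    svg_bytes: bytes,
    out_dir,
    basename: str = "enrichment",
    png: bool = False,
) -> dict[str, Path]:
    """Write the table (TSV), the schematic (SVG) and optionally a PNG."""
    from .enrichment import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / f"{basename}.tsv",
        "svg": out_dir / f"{basename}.svg",
    }
    write_table(table, paths["tsv"])
    paths["svg"].write_bytes(svg_bytes)
    if png:
        paths["png"] = out_dir / f"{basename}.png"
        paths["png"].write_bytes(rasterize(svg_bytes))
    return paths
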