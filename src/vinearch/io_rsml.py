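"""Read and write digitized whole-plant geometry.

Three formats are supported:

* **RSML** (Root System Markup Language 1.0) — XML interchange format for
  root architecture, ``scene → plant → nested root`` hierarchy with per-root
  polyline geometry. All coordinates are centimetres; a file declaring any
  other unit is rejected rather than silently rescaled.
* **Digitized point tables** — CSV transcripts of an electromagnetic
  digitizer session with header ``plant_id, organ, label, x, y, z``, one row
  per captured point in digitization order. See
  :func:`read_digitized_points` for the label conventions.
* **VTK PolyData (.vtp)** — XML export for 3-D visualization, one polyline
  cell per axis with an organ-type cell array.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    CompartmentWeights,
    LeafLandmarks,
    Phytomer,
    PlantArchitecture,
    Root,
    RootSystem,
    ShootAxis,
    ShootSystem,
    TopologyError,
    UnitError,
    ValidationError,
    flatten_segments,
)

__all__ = [
    "read_rsml",
    "write_rsml",
    "read_digitized_points",
    "export_vtp",
    "flatten_segments",
]

_KNOWN_META = {"genotype", "time_point", "stem_base_z", "soil_surface_z",
               "root_dry_weight", "stem_dry_weight", "shoot_dry_weight",
               "leaf_dry_weight"}


def _fmt(v: float) -> str:
    return format(float(v), ".8g")


# ---------------------------------------------------------------------------
# RSML

def read_rsml(path: Union[str, Path], flip_z: bool = False) -> PlantArchitecture:
    """Read an RSML file into a :class:`PlantArchitecture`.

    Parameters
    ----------
    path : path-like
        RSML 1.0 XML file. The metadata ``<unit>`` must be ``cm`` (or a
        recognized synonym); anything else raises :class:`UnitError`.
    flip_z : bool
        Negate z on read. Some depositors store depth as positive-down
        coordinates; this flag converts them to this package's
        positive-up convention instead of guessing from the data.

    Raises
    ------
    ValueError
        Malformed XML (the message names the offending line).
    ValidationError
        A root element has fewer than two polyline points.
    UnitError
        Unknown or non-centimetre length unit.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as e:
        line, col = e.position
        raise ValueError(f"{path}: malformed XML at line {line}, column {col}: "
                         f"{e.msg if hasattr(e, 'msg') else e}") from e
    rsml = tree.getroot()

    unit = None
    meta = rsml.find("metadata")
    if meta is not None:
        u = meta.find("unit")
        if u is not None and u.text:
            unit = u.text.strip()
    if unit is not None and unit.lower() not in {"cm", "centimeter", "centimetre"}:
        raise UnitError(f"{path}: declared unit {unit!r} is not centimetres; "
                        "refusing to rescale silently")

    scene = rsml.find("scene")
    plant = scene.find("plant") if scene is not None else None
    if plant is None:
        raise ValidationError(f"{path}: no scene/plant element")

    props = _read_properties(plant)
    zsign = -1.0 if flip_z else 1.0

    roots: list[Root] = []

    def walk(elem: ET.Element, parent_id: Optional[str], order: int) -> None:
        rid = elem.get("ID") or elem.get("id") or f"root{len(roots) + 1}"
        geom = elem.find("geometry")
        poly = geom.find("polyline") if geom is not None else None
        pts = []
        if poly is not None:
            for p in poly.findall("point"):
                pts.append((float(p.get("x")), float(p.get("y")),
                            zsign * float(p.get("z"))))
        if len(pts) < 2:
            raise ValidationError(
                f"{path}: root {rid!r} has {len(pts)} polyline point(s); >= 2 required")
        rprops = _read_properties(elem)
        roots.append(Root(id=rid, polyline=np.asarray(pts), parent_id=parent_id,
                          order=order, properties=rprops))
        for child in elem.findall("root"):
            walk(child, rid, order + 1)

    for top in plant.findall("root"):
        walk(top, None, 0)

    weights = CompartmentWeights(
        root=_popf(props, "root_dry_weight"),
        stem=_popf(props, "stem_dry_weight"),
        shoot=_popf(props, "shoot_dry_weight"),
        leaf=_popf(props, "leaf_dry_weight"),
    )
    arch = PlantArchitecture(
        plant_id=plant.get("id") or path.stem,
        roots=RootSystem(roots),
        genotype=str(props.pop("genotype", "")),
        time_point=str(props.pop("time_point", "")),
        stem_base_z=float(props.pop("stem_base_z", -25.0)),
        soil_surface_z=float(props.pop("soil_surface_z", -5.0)),
        weights=weights,
    )
    return arch


def _read_properties(elem: ET.Element) -> dict:
    out: dict = {}
    props = elem.find("properties")
    if props is not None:
        for p in props.findall("property"):
            out[p.get("name")] = p.get("value")
    return out


def _popf(props: dict, key: str) -> Optional[float]:
    v = props.pop(key, None)
    return None if v is None else float(v)


def write_rsml(arch: PlantArchitecture, path: Union[str, Path]) -> Path:
    """Write an architecture as RSML 1.0 XML (unit metadata ``cm``).

    Geometry survives a read/write round trip to better than 1e-4 cm;
    topology (element nesting) is reproduced exactly. Per-root opaque
    properties are carried along unmodified.
    """
    path = Path(path)
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "software").text = "vinearch"

    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id=arch.plant_id)
    props = {
        "genotype": arch.genotype,
        "time_point": arch.time_point,
        "stem_base_z": _fmt(arch.stem_base_z),
        "soil_surface_z": _fmt(arch.soil_surface_z),
    }
    for comp in ("root", "stem", "shoot", "leaf"):
        w = getattr(arch.weights, comp)
        if w is not None:
            props[f"{comp}_dry_weight"] = _fmt(w)
    _write_properties(plant, props)

    children: dict[Optional[str], list[Root]] = {}
    for r in arch.roots:
        children.setdefault(r.parent_id, []).append(r)

    def emit(parent_elem: ET.Element, root: Root) -> None:
        el = ET.SubElement(parent_elem, "root", ID=root.id)
        if root.properties:
            _write_properties(el, {k: str(v) for k, v in root.properties.items()})
        geom = ET.SubElement(el, "geometry")
        poly = ET.SubElement(geom, "polyline")
        for x, y, z in root.polyline:
            ET.SubElement(poly, "point", x=_fmt(x), y=_fmt(y), z=_fmt(z))
        for child in children.get(root.id, []):
            emit(el, child)

    for top in children.get(None, []):
        emit(plant, top)

    ET.indent(rsml)
    ET.ElementTree(rsml).write(str(path), encoding="unicode", xml_declaration=True)
    return path


def _write_properties(elem: ET.Element, props: dict) -> None:
    pe = ET.SubElement(elem, "properties")
    for k, v in props.items():
        ET.SubElement(pe, "property", name=str(k), value=str(v))


# ---------------------------------------------------------------------------
# Digitized point tables

def read_digitized_points(table: Union[str, Path, pd.DataFrame],
                          plant_id: Optional[str] = None) -> PlantArchitecture:
    """Reconstruct a plant from a digitizer point table.

    The table (CSV path or DataFrame) has columns
    ``plant_id, organ, label, x, y, z`` with rows in digitization order.
    Conventions, mirroring the field protocol (graft point first, then the
    shoot initiation point, then node by node, laterals hooked onto their
    mother nodes):

    * ``organ == "stem"`` — below-graft stem polyline, label is a running
      index. Stored as stem geometry, never counted as root length.
    * ``organ == "main"`` — label is an integer: ``0`` the grafting point,
      ``1`` the shoot initiation point (both form the shoot base path),
      ``2, 3, ...`` phytomer nodes at ranks ``1, 2, ...``.
    * ``organ == "lateral"`` — label ``"<mother_rank>.<i>"``; the lateral's
      i-th node attached at main-axis phytomer ``mother_rank``. A mother
      rank with no main-axis node raises :class:`TopologyError`.
    * ``organ == "leaf"`` — label ``PL1..PL6``; the six rows attach to the
      most recently digitized shoot node (main or lateral), exactly as the
      operator records a leaf right after its node. A leaf with a number of
      points other than six raises :class:`ValidationError`.
    * ``organ == "root"`` — label is a dotted root id; ``"r1.2"`` is a
      child of ``"r1"``. Rows sharing a label form one polyline.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, dtype={"label": str, "organ": str, "plant_id": str})
    else:
        df = table.copy()
        df["label"] = df["label"].astype(str)
    required = {"plant_id", "organ", "label", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"point table missing columns: {sorted(missing)}")
    if plant_id is None:
        ids = df["plant_id"].unique()
        if len(ids) != 1:
            raise ValidationError(
                f"table holds {len(ids)} plants; pass plant_id to select one")
        plant_id = str(ids[0])
    else:
        df = df[df["plant_id"].astype(str) == str(plant_id)]

    stem_pts: list[np.ndarray] = []
    main_nodes: dict[int, np.ndarray] = {}
    base: dict[int, np.ndarray] = {}
    laterals: dict[int, list[np.ndarray]] = {}
    # leaf accumulation keyed by the node that was digitized last
    current_node: Optional[tuple] = None  # ("main", rank) or ("lat", mother, i)
    leaf_buf: dict[tuple, list[tuple[str, np.ndarray]]] = {}

    for row in df.itertuples(index=False):
        organ = str(row.organ).strip().lower()
        xyz = np.array([row.x, row.y, row.z], dtype=float)
        label = str(row.label).strip()
        if organ == "stem":
            stem_pts.append(xyz)
        elif organ in ("main", "main_shoot"):
            k = int(float(label))
            if k <= 1:
                base[k] = xyz
            else:
                main_nodes[k - 1] = xyz
                current_node = ("main", k - 1)
        elif organ == "lateral":
            mother_s, _, idx_s = label.partition(".")
            mother = int(mother_s)
            laterals.setdefault(mother, []).append(xyz)
            current_node = ("lat", mother, len(laterals[mother]))
        elif organ == "leaf":
            if current_node is None:
                raise TopologyError(
                    f"plant {plant_id}: leaf point {label} digitized before any shoot node")
            leaf_buf.setdefault(current_node, []).append((label.upper(), xyz))
        elif organ == "root":
            pass  # handled below, order-preserving groupby
        else:
            raise ValidationError(f"plant {plant_id}: unknown organ code {organ!r}")

    # roots: group rows by label preserving digitization order
    rdf = df[df["organ"].str.strip().str.lower() == "root"]
    roots: list[Root] = []
    for rid, grp in rdf.groupby("label", sort=False):
        poly = grp[["x", "y", "z"]].to_numpy(dtype=float)
        parent = rid.rpartition(".")[0] or None
        roots.append(Root(id=str(rid), polyline=poly, parent_id=parent,
                          order=str(rid).count(".")))

    shoots = None
    if main_nodes:
        ranks = sorted(main_nodes)
        if ranks != list(range(1, len(ranks) + 1)):
            raise TopologyError(f"plant {plant_id}: main-axis ranks not consecutive: {ranks}")
        for mother in laterals:
            if mother not in main_nodes:
                raise TopologyError(
                    f"plant {plant_id}: lateral references missing mother node {mother}")
        phytomers = [Phytomer(node=main_nodes[r], rank=r) for r in ranks]
        for mother, pts in laterals.items():
            lat = ShootAxis([Phytomer(node=p, rank=i + 1) for i, p in enumerate(pts)])
            phytomers[mother - 1].lateral = lat
        main = ShootAxis(phytomers, is_main=True)
        # attach leaves
        for key, pl in leaf_buf.items():
            labels = [lab for lab, _ in pl]
            if sorted(labels) != [f"PL{i}" for i in range(1, 7)]:
                raise ValidationError(
                    f"plant {plant_id}: leaf at node {key} has labels {labels}; "
                    "exactly PL1..PL6 required")
            pts6 = np.vstack([dict(pl)[f"PL{i}"] for i in range(1, 7)])
            leaf = LeafLandmarks(pts6)
            if key[0] == "main":
                main.phytomers[key[1] - 1].leaf = leaf
            else:
                _, mother, i = key
                main.phytomers[mother - 1].lateral.phytomers[i - 1].leaf = leaf
        bp = None
        if base:
            bp = np.vstack([base[k] for k in sorted(base)] +
                           ([main_nodes[1]] if 1 in main_nodes else []))
        shoots = ShootSystem(main=main, base_path=bp)

    return PlantArchitecture(
        plant_id=plant_id,
        roots=RootSystem(roots),
        shoots=shoots,
        stem=np.vstack(stem_pts) if len(stem_pts) >= 2 else None,
    )


# ---------------------------------------------------------------------------
# VTK PolyData export

_ORGAN_CODES = {"root": 0, "stem": 1, "main_shoot": 2, "lateral_shoot": 3}


def export_vtp(arch: PlantArchitecture, path: Union[str, Path]) -> Path:
    """Export all axes as a VTK PolyData (.vtp) XML file.

    One polyline cell per root / stem / shoot axis; a cell-data array
    ``organ`` codes the axis type (0 root, 1 stem, 2 main shoot,
    3 lateral shoot). Readable by ParaView and any VTK XML reader.
    """
    path = Path(path)
    polylines: list[np.ndarray] = []
    organ: list[int] = []
    for r in arch.roots:
        polylines.append(r.polyline)
        organ.append(_ORGAN_CODES["root"])
    if arch.stem is not None:
        polylines.append(arch.stem)
        organ.append(_ORGAN_CODES["stem"])
    if arch.shoots is not None and arch.shoots.main is not None:
        polylines.append(arch.shoots.main.nodes)
        organ.append(_ORGAN_CODES["main_shoot"])
        for lat in arch.shoots.laterals:
            polylines.append(lat.nodes)
            organ.append(_ORGAN_CODES["lateral_shoot"])

    n_points = int(sum(len(p) for p in polylines))
    n_cells = len(polylines)
    buf = io.StringIO()
    buf.write('<?xml version="1.0"?>\n')
    buf.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
    buf.write('  <PolyData>\n')
    buf.write(f'    <Piece NumberOfPoints="{n_points}" NumberOfVerts="0" '
              f'NumberOfLines="{n_cells}" NumberOfStrips="0" NumberOfPolys="0">\n')
    buf.write('      <Points>\n        <DataArray type="Float64" '
              'NumberOfComponents="3" format="ascii">\n')
    for p in polylines:
        for x, y, z in p:
            buf.write(f"          {_fmt(x)} {_fmt(y)} {_fmt(z)}\n")
    buf.write('        </DataArray>\n      </Points>\n')
    buf.write('      <Lines>\n        <DataArray type="Int64" Name="connectivity" '
              'format="ascii">\n')
    offset = 0
    offsets = []
    for p in polylines:
        idx = " ".join(str(offset + i) for i in range(len(p)))
        buf.write(f"          {idx}\n")
        offset += len(p)
        offsets.append(offset)
    buf.write('        </DataArray>\n        <DataArray type="Int64" '
              'Name="offsets" format="ascii">\n')
    buf.write("          " + " ".join(map(str, offsets)) + "\n")
    buf.write('        </DataArray>\n      </Lines>\n')
    buf.write('      <CellData Scalars="organ">\n        <DataArray type="Int32" '
              'Name="organ" format="ascii">\n')
    buf.write("          " + " ".join(map(str, organ)) + "\n")
    buf.write('        </DataArray>\n      </CellData>\n')
    buf.write('    </Piece>\n  </PolyData>\n</VTKFile>\n')
    path.write_text(buf.getvalue())
    return path
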