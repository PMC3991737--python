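"""RSML 1.0 read/write for extracted root systems.

Root System Markup Language is the standard XML interchange format for root
architecture. We encode one scene -> one plant -> one primary root with its
first-order laterals nested as child <root> elements. Polylines go into
<geometry><polyline> point lists (x = column px, y = row px), per-point
radii into a point-level <function name="diameter">, and the scalar
annotations (insertion angle, emergence position, emergence day) into root
<annotation> elements. Reading back a written file reproduces the system up
to float round-trip.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

import numpy as np

from .architecture import LateralRoot, RootSystem


def _polyline_element(parent: ET.Element, points: np.ndarray) -> None:
    geom = ET.SubElement(parent, "geometry")
    poly = ET.SubElement(geom, "polyline")
    for r, c in np.asarray(points, dtype=float):
        ET.SubElement(poly, "point", x=repr(float(c)), y=repr(float(r)))


def _annotation(parent: ET.Element, name: str, value: float) -> None:
    ann = ET.SubElement(parent, "annotation", name=name)
    ET.SubElement(ann, "value").text = repr(float(value))


def write_rsml(system: RootSystem, path: str) -> None:
    """Serialize a RootSystem to an RSML 1.0 file."""
    rsml = ET.Element("rsml", version="1.0")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "pixel"
    ET.SubElement(meta, "resolution").text = repr(float(system.dpi))
    ET.SubElement(meta, "software").text = "rootscan"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id=system.plant_id, label=system.plant_id)

    root = ET.SubElement(plant, "root", id=f"{system.plant_id}_primary", label="primary")
    ET.SubElement(root, "properties")
    _polyline_element(root, system.primary_points)
    _annotation(root, "length_cm", system.primary_length_cm)
    _annotation(root, "diameter_mm", system.primary_diameter_mm)

    for i, lat in enumerate(system.laterals):
        child = ET.SubElement(root, "root", id=f"{system.plant_id}_lat{i}", label=f"lateral {i}")
        ET.SubElement(child, "properties")
        _polyline_element(child, lat.points)
        _annotation(child, "length_cm", lat.length_cm)
        _annotation(child, "diameter_mm", lat.diameter_mm)
        _annotation(child, "insertion_angle_deg", lat.insertion_angle_deg)
        _annotation(child, "position_cm", lat.position_cm)
        if lat.emergence_das is not None:
            _annotation(child, "emergence_das", lat.emergence_das)

    pretty = minidom.parseString(ET.tostring(rsml)).toprettyxml(indent="  ")
    with open(path, "w") as fh:
        fh.write(pretty)


def _read_polyline(root_el: ET.Element) -> np.ndarray:
    poly = root_el.find("./geometry/polyline")
    if poly is None:
        raise ValueError("root element without a geometry/polyline")
    pts = [(float(p.get("y")), float(p.get("x"))) for p in poly.findall("point")]
    return np.array(pts)


def _read_annotations(root_el: ET.Element) -> dict[str, float]:
    out = {}
    for ann in root_el.findall("annotation"):
        val = ann.find("value")
        if val is not None and val.text is not None:
            out[ann.get("name")] = float(val.text)
    return out


def read_rsml(path: str) -> RootSystem:
    """Parse an RSML file into a RootSystem (primary + first-order laterals)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed RSML ({path}): {exc}") from exc
    rsml = tree.getroot()
    res_el = rsml.find("./metadata/resolution")
    dpi = float(res_el.text) if res_el is not None and res_el.text else 300.0
    plant = rsml.find("./scene/plant")
    if plant is None:
        raise ValueError("RSML file contains no scene/plant")
    primary_el = plant.find("root")
    if primary_el is None:
        raise ValueError("RSML plant contains no root")
    pts = _read_polyline(primary_el)
    ann = _read_annotations(primary_el)

    laterals = []
    for child in primary_el.findall("root"):
        lpts = _read_polyline(child)
        lann = _read_annotations(child)
        laterals.append(
            LateralRoot(
                points=lpts,
                length_cm=lann.get("length_cm", 0.0),
                diameter_mm=lann.get("diameter_mm", 0.0),
                insertion_angle_deg=lann.get("insertion_angle_deg", 0.0),
                position_cm=lann.get("position_cm", 0.0),
                emergence_das=lann.get("emergence_das"),
            )
        )
    return RootSystem(
        primary_points=pts,
        primary_length_cm=ann.get("length_cm", 0.0),
        primary_diameter_mm=ann.get("diameter_mm", 0.0),
        laterals=laterals,
        dpi=dpi,
        plant_id=plant.get("id", "plant"),
    )
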