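"""File formats: VTU meshes, CSV traces/tables, HDF5 histories, YAML configs.

Meshes travel as ASCII XML VTU (unstructured tetrahedral grids) with the
region label as cell data and phi / z / layer (and optionally the fiber
triad) as point data, so results open directly in ParaView.  The writer
and reader cover the plain ASCII subset of the format.
"""

import xml.etree.ElementTree as ET
from pathlib import Path

import h5py
import numpy as np
import yaml

from ventric.anatomy import Mesh
from ventric.errors import ConfigurationError


def write_vtu(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None):
    """Write a labeled tetrahedral mesh as ASCII XML VTU."""
    pd = {"phi": mesh.phi, "z": mesh.z, "layer": mesh.layer}
    if point_data:
        pd.update(point_data)
    cd = {"region": mesh.region}
    if cell_data:
        cd.update(cell_data)
    n, m = mesh.n_nodes, mesh.n_elements

    def arr(parent, name, data, ncomp=1):
        data = np.asarray(data)
        typ = "Int32" if np.issubdtype(data.dtype, np.integer) else "Float64"
        el = ET.SubElement(parent, "DataArray", Name=name, type=typ,
                           NumberOfComponents=str(ncomp), format="ascii")
        el.text = " ".join(map(str, data.ravel()))
        return el

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(n), NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    arr(pts, "Points", mesh.nodes, 3)
    cells = ET.SubElement(piece, "Cells")
    arr(cells, "connectivity", mesh.tets.astype(np.int32))
    arr(cells, "offsets", (np.arange(1, m + 1) * 4).astype(np.int32))
    arr(cells, "types", np.full(m, 10, dtype=np.int32))  # VTK_TETRA
    pdata = ET.SubElement(piece, "PointData")
    for name, data in pd.items():
        data = np.asarray(data)
        arr(pdata, name, data, 3 if data.ndim == 2 else 1)
    cdata = ET.SubElement(piece, "CellData")
    for name, data in cd.items():
        data = np.asarray(data)
        arr(cdata, name, data, 3 if data.ndim == 2 else 1)
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtu(path) -> Mesh:
    """Read an ASCII VTU tetrahedral mesh written by this package (or any
    plain-ASCII VTU carrying tetrahedra and the same array names)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(el, dtype=float):
        return np.fromstring(el.text.replace("\n", " "), sep=" ", dtype=dtype)

    def find_array(parent, name):
        for el in parent.iter("DataArray"):
            if el.get("Name") == name:
                return el
        return None

    pts = parse(find_array(piece.find("Points"), "Points")).reshape(-1, 3)
    cells = piece.find("Cells")
    types = parse(find_array(cells, "types"), int)
    if not np.all(types == 10):
        raise ConfigurationError("only tetrahedral (type 10) VTU meshes are supported")
    conn = parse(find_array(cells, "connectivity"), int).reshape(-1, 4)
    n = pts.shape[0]

    def point_arr(name, default, dtype=float):
        el = find_array(piece.find("PointData"), name) if piece.find("PointData") is not None else None
        return parse(el, dtype) if el is not None else default

    cd = piece.find("CellData")
    region_el = find_array(cd, "region") if cd is not None else None
    region = (parse(region_el, int) if region_el is not None
              else np.zeros(conn.shape[0], dtype=int))
    phi = point_arr("phi", np.zeros(n))
    z = point_arr("z", np.zeros(n))
    layer = point_arr("layer", np.digitize(phi, (0.3, 0.7)), int)
    return Mesh(pts, conn, region, phi, z, layer,
                metadata={"kind": "imported", "source": str(path)})


def write_history_h5(path, result, mesh: Mesh | None = None):
    """Store a SimulationResult's potential history and maps in HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=result.t_snap)
        f.create_dataset("v_mV", data=result.v_snap, compression="gzip")
        f.create_dataset("lat_ms", data=result.lat)
        f.create_dataset("rt90_ms", data=result.rt90)
        f.attrs["config"] = yaml.safe_dump(result.config)
        if mesh is not None:
            f.create_dataset("nodes_cm", data=mesh.nodes)
            f.create_dataset("tets", data=mesh.tets)
            f.create_dataset("region", data=mesh.region)


def write_config(path, config: dict):
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
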