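"""File formats and in-memory containers shared by all pipeline stages.

Formats are deliberately plain text:

* spectra and 1-D curves: comma-separated columns with ``#``-prefixed
  ``key=value`` metadata lines (decimal point, no locale handling);
* trajectories: extended XYZ (comment line carrying ``Lattice=`` and
  ``time=``) or the GRO dialect (nm, converted to Å on read);
* topology: a tab-separated sidecar assigning each atom a molecule id and
  a role token, because XYZ frames carry no molecule identity.

Downstream stages consume only the containers defined here; no other
module reads files directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParseError",
    "SpectrumTable",
    "CurveTable",
    "Topology",
    "Trajectory",
    "VALID_ROLES",
    "load_spectra",
    "write_spectra",
    "load_curve",
    "write_curve",
    "load_topology",
    "write_topology",
    "load_trajectory",
    "write_trajectory_xyz",
]

#: Recognized atom role tokens: water oxygen/hydrogen, PEG ether oxygen,
#: PEG backbone carbon and hydrogen.
VALID_ROLES = ("OW", "HW", "O_ether", "C", "H_peg")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# --------------------------------------------------------------------------
# containers


@dataclass
class SpectrumTable:
    """Reduced spectrum S(q, ΔE) at one temperature.

    Rows are grouped by momentum transfer ``q`` (Å⁻¹); within each group the
    energy-transfer grid ``dE`` (μeV) is strictly increasing. ``S`` carries
    arbitrary intensity units and ``err`` its one-sigma uncertainty.
    """

    temperature: float
    q: np.ndarray
    dE: np.ndarray
    S: np.ndarray
    err: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.dE = np.asarray(self.dE, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.err = np.asarray(self.err, dtype=float)
        n = len(self.q)
        if not (len(self.dE) == len(self.S) == len(self.err) == n):
            raise ValueError("spectrum columns have unequal lengths")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(self.err < 0):
            raise ValueError("err must be non-negative")
        for qv in self.q_values():
            grid = self.dE[self.q == qv]
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"dE grid not strictly increasing for q={qv}")

    def q_values(self) -> np.ndarray:
        """Distinct q values in first-appearance order."""
        _, idx = np.unique(self.q, return_index=True)
        return self.q[np.sort(idx)]

    def group(self, qv: float, atol: float = 1e-9):
        """Return (dE, S, err) arrays for the row group at momentum ``qv``."""
        mask = np.isclose(self.q, qv, rtol=0.0, atol=atol)
        if not np.any(mask):
            raise KeyError(f"no rows at q={qv}")
        return self.dE[mask], self.S[mask], self.err[mask]


@dataclass
class CurveTable:
    """Generic 1-D curve (x, y, err) with free-form metadata.

    Carrier for I(q), F(q,t), elastic scans, correlation functions and
    τ(T) tables; ``metadata`` keys such as ``temperature``, ``q`` or
    ``label`` travel with the data through ``#`` comment lines on disk.
    """

    x: np.ndarray
    y: np.ndarray
    err: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if len(self.err) != len(self.x):
                raise ValueError("err length mismatch")
            if np.any(self.err < 0):
                raise ValueError("err must be non-negative")
        if len(self.x) != len(self.y):
            raise ValueError("x/y length mismatch")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        data = {"x": self.x, "y": self.y}
        if self.err is not None:
            data["err"] = self.err
        return pd.DataFrame(data)


@dataclass
class Topology:
    """Per-atom molecule membership and role assignment (0-based indices)."""

    index: np.ndarray
    molecule_id: np.ndarray
    molecule_type: np.ndarray
    role: np.ndarray

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.molecule_type = np.asarray(self.molecule_type, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        n = len(self.index)
        if not (len(self.molecule_id) == len(self.molecule_type) == len(self.role) == n):
            raise ValueError("topology columns have unequal lengths")
        if sorted(self.index.tolist()) != list(range(n)):
            raise ValueError("atom indices must be 0..n-1, each exactly once")
        bad = set(self.role.tolist()) - set(VALID_ROLES)
        if bad:
            raise ParseError(f"unknown role token(s): {sorted(bad)}")
        # water sanity: one OW per WAT molecule, 0 or 2 HW (bare-oxygen
        # walkers from synthetic trajectories are legal)
        for mid in np.unique(self.molecule_id[self.molecule_type == "WAT"]):
            roles = self.role[self.molecule_id == mid]
            n_ow = int(np.sum(roles == "OW"))
            n_hw = int(np.sum(roles == "HW"))
            if n_ow != 1 or n_hw not in (0, 2):
                raise ValueError(
                    f"WAT molecule {mid} must have one OW and zero or two HW "
                    f"(got {n_ow} OW, {n_hw} HW)"
                )

    def __len__(self) -> int:
        return len(self.index)

    def select(self, roles) -> np.ndarray:
        """Indices of atoms whose role is in ``roles``."""
        if isinstance(roles, str):
            roles = (roles,)
        mask = np.isin(self.role.astype(str), list(roles))
        return self.index[mask]


@dataclass
class Trajectory:
    """Frame sequence with orthorhombic periodic boxes.

    ``positions`` has shape (n_frames, n_atoms, 3) in Å; ``boxes`` holds the
    three edge lengths per frame in Å; ``timestep`` is the uniform frame
    spacing in ps (0.0 for a single frame).
    """

    timestep: float
    boxes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, atoms, 3)")
        if self.boxes.shape != (self.positions.shape[0], 3):
            raise ValueError("boxes must have shape (frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


# --------------------------------------------------------------------------
# CSV spectra / curves


def _parse_metadata_line(line: str) -> tuple[str, str] | None:
    body = line.lstrip("#").strip()
    if "=" in body:
        key, _, value = body.partition("=")
        return key.strip(), value.strip()
    return None


def load_spectra(path) -> SpectrumTable:
    """Read a single-temperature spectrum table.

    The file is comma-separated with header ``q,dE,S,err``; the temperature
    is stated in a ``# temperature=<K>`` comment line.
    """
    path = Path(path)
    temperature = None
    header = None
    cols: list[list[float]] = [[], [], [], []]
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                kv = _parse_metadata_line(line)
                if kv and kv[0] == "temperature":
                    temperature = float(kv[1])
                continue
            if header is None:
                header = [t.strip() for t in line.split(",")]
                required = ["q", "dE", "S", "err"]
                if header[: len(required)] != required:
                    missing = [c for c in required if c not in header]
                    raise ParseError(
                        f"{path}:{lineno}: header must be 'q,dE,S,err'"
                        + (f" (missing column {missing[0]})" if missing else "")
                    )
                continue
            parts = line.split(",")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                values = [float(p) for p in parts[:4]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if values[3] < 0:
                raise ParseError(f"{path}:{lineno}: negative err")
            for c, v in zip(cols, values):
                c.append(v)
    if temperature is None:
        raise ParseError(f"{path}: missing '# temperature=' metadata line")
    if header is None or not cols[0]:
        raise ParseError(f"{path}: no data rows")
    q, dE, S, err = (np.array(c) for c in cols)
    # per-q monotonicity with a line-numbered message
    for qv in np.unique(q):
        rows = np.flatnonzero(q == qv)
        grid = dE[rows]
        bad = np.flatnonzero(np.diff(grid) <= 0)
        if bad.size:
            # +2 skips header; metadata/blank lines before data are rare in
            # our own files, so recompute the true line by re-scanning
            lineno = _data_line_number(path, rows[bad[0] + 1])
            raise ParseError(f"{path}:{lineno}: dE grid not increasing for q={qv}")
    return SpectrumTable(temperature=temperature, q=q, dE=dE, S=S, err=err)


def _data_line_number(path: Path, row: int) -> int:
    """Physical line number of 0-based data row ``row`` (after the header)."""
    seen = -2  # first non-comment line is the header (row -1)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seen += 1
            if seen == row:
                return lineno
    return -1


from contextlib import contextmanager


@contextmanager
def _open_out(path):
    if hasattr(path, "write"):
        yield path
    else:
        with open(path, "w") as fh:
            yield fh


def write_spectra(table: SpectrumTable, path) -> None:
    with _open_out(path) as fh:
        fh.write(f"# temperature={float(table.temperature)!r}\n")
        fh.write("q,dE,S,err\n")
        for q, dE, S, err in zip(table.q, table.dE, table.S, table.err):
            fh.write(f"{float(q)!r},{float(dE)!r},{float(S)!r},{float(err)!r}\n")


def load_curve(path) -> CurveTable:
    """Read an (x, y[, err]) curve; ``#`` comments become metadata."""
    path = Path(path)
    metadata: dict = {}
    header = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                kv = _parse_metadata_line(line)
                if kv:
                    key, value = kv
                    try:
                        metadata[key] = float(value)
                    except ValueError:
                        metadata[key] = value
                continue
            if header is None:
                header = [t.strip() for t in line.split(",")]
                continue
            try:
                rows.append([float(p) for p in line.split(",")])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if header is None or not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows)
    err = arr[:, 2] if arr.shape[1] > 2 else None
    return CurveTable(x=arr[:, 0], y=arr[:, 1], err=err, metadata=metadata)


def write_curve(curve: CurveTable, path, x_label: str = "x", y_label: str = "y") -> None:
    with _open_out(path) as fh:
        for key, value in curve.metadata.items():
            fh.write(f"# {key}={value}\n")
        cols = [x_label, y_label] + (["err"] if curve.err is not None else [])
        fh.write(",".join(cols) + "\n")
        for i in range(len(curve.x)):
            row = [repr(float(curve.x[i])), repr(float(curve.y[i]))]
            if curve.err is not None:
                row.append(repr(float(curve.err[i])))
            fh.write(",".join(row) + "\n")


# --------------------------------------------------------------------------
# topology


def load_topology(path) -> Topology:
    """Read the tab-separated topology sidecar.

    Columns: ``index  molecule_id  molecule_type  role``.
    """
    path = Path(path)
    header = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [t.strip() for t in parts]
                if header[:4] != ["index", "molecule_id", "molecule_type", "role"]:
                    raise ParseError(f"{path}:{lineno}: bad topology header")
                continue
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            role = parts[3].strip()
            if role not in VALID_ROLES:
                raise ParseError(f"{path}:{lineno}: unknown role token '{role}'")
            rows.append((int(parts[0]), int(parts[1]), parts[2].strip(), role))
    if not rows:
        raise ParseError(f"{path}: no atoms")
    idx, mid, mtype, role = zip(*rows)
    return Topology(
        index=np.array(idx),
        molecule_id=np.array(mid),
        molecule_type=np.array(mtype, dtype=object),
        role=np.array(role, dtype=object),
    )


def write_topology(top: Topology, path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tmolecule_id\tmolecule_type\trole\n")
        for i in range(len(top)):
            fh.write(
                f"{top.index[i]}\t{top.molecule_id[i]}\t{top.molecule_type[i]}\t{top.role[i]}\n"
            )


# --------------------------------------------------------------------------
# trajectories

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"time=([-+0-9.eE]+)")


def _orthorhombic_edges(lattice: np.ndarray, where: str) -> np.ndarray:
    off = lattice - np.diag(np.diag(lattice))
    if np.max(np.abs(off)) > 1e-8:
        raise ParseError(f"{where}: triclinic lattice not supported (orthorhombic only)")
    edges = np.diag(lattice)
    if np.any(edges <= 0):
        raise ParseError(f"{where}: box edges must be positive")
    return edges


def _load_extxyz(path: Path):
    frames, boxes, times = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from None
        if i + 1 >= n_lines:
            raise ParseError(f"{path}:{i + 1}: truncated frame")
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if m is None:
            raise ParseError(f"{path}:{i + 2}: comment line lacks Lattice=")
        nums = [float(t) for t in m.group(1).split()]
        if len(nums) != 9:
            raise ParseError(f"{path}:{i + 2}: Lattice= must have 9 numbers")
        edges = _orthorhombic_edges(np.array(nums).reshape(3, 3), f"{path}:{i + 2}")
        mt = _TIME_RE.search(comment)
        times.append(float(mt.group(1)) if mt else float(len(times)))
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ParseError(f"{path}:{i + 1}: frame shorter than declared atom count")
        pos = np.empty((n_atoms, 3))
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + j}: expected 'symbol x y z'")
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(pos)
        boxes.append(edges)
        i += 2 + n_atoms
    return frames, boxes, times


def _load_gro(path: Path):
    """GRO dialect: title (optional ``t=`` time in ps), count, fixed-width
    atom lines, box line. Coordinates are nm on disk, Å in memory."""
    frames, boxes, times = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        mt = re.search(r"t=\s*([-+0-9.eE]+)", title)
        times.append(float(mt.group(1)) if mt else float(len(times)))
        try:
            n_atoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{i + 2}: expected atom count") from None
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ParseError(f"{path}:{i + 2}: truncated frame")
        pos = np.empty((n_atoms, 3))
        for j, row in enumerate(block):
            try:
                pos[j] = [float(row[20:28]), float(row[28:36]), float(row[36:44])]
            except ValueError:
                raise ParseError(f"{path}:{i + 3 + j}: malformed GRO atom line") from None
        box_parts = lines[i + 2 + n_atoms].split()
        if len(box_parts) < 3:
            raise ParseError(f"{path}:{i + 3 + n_atoms}: malformed box line")
        if len(box_parts) > 3 and any(abs(float(v)) > 1e-10 for v in box_parts[3:]):
            raise ParseError(f"{path}:{i + 3 + n_atoms}: triclinic box not supported")
        edges = np.array([float(v) for v in box_parts[:3]]) * 10.0  # nm → Å
        frames.append(pos * 10.0)
        boxes.append(edges)
        i += 3 + n_atoms
    return frames, boxes, times


def load_trajectory(frames_path, topology_path) -> tuple[Trajectory, Topology]:
    """Load a frame sequence plus its topology sidecar.

    The timestep is inferred from successive ``time=`` values and must be
    uniform to 1e-6 ps; atom counts must agree between the two files.
    """
    frames_path = Path(frames_path)
    topology = load_topology(topology_path)
    if frames_path.suffix.lower() == ".gro":
        frames, boxes, times = _load_gro(frames_path)
    else:
        frames, boxes, times = _load_extxyz(frames_path)
    if not frames:
        raise ParseError(f"{frames_path}: no frames")
    n_atoms = frames[0].shape[0]
    for k, f in enumerate(frames):
        if f.shape[0] != n_atoms:
            raise ParseError(f"{frames_path}: frame {k} has {f.shape[0]} atoms, expected {n_atoms}")
    if n_atoms != len(topology):
        raise ParseError(
            f"atom-count mismatch: topology lists {len(topology)} atoms, "
            f"frames carry {n_atoms}"
        )
    if len(times) > 1:
        dts = np.diff(times)
        if np.any(dts <= 0) or np.max(np.abs(dts - dts[0])) > 1e-6:
            raise ParseError(f"{frames_path}: non-uniform timestep (time= values)")
        timestep = float(dts[0])
    else:
        timestep = 0.0
    traj = Trajectory(timestep=timestep, boxes=np.array(boxes), positions=np.array(frames))
    return traj, topology


def write_trajectory_xyz(traj: Trajectory, top: Topology, path, t0: float = 0.0) -> None:
    """Write extended XYZ; role tokens double as element symbols."""
    symbol = {"OW": "O", "HW": "H", "O_ether": "O", "C": "C", "H_peg": "H"}
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            a, b, c = (float(v) for v in traj.boxes[k])
            t = t0 + k * traj.timestep
            fh.write(f"{traj.n_atoms}\n")
            fh.write(
                f'Lattice="{a!r} 0.0 0.0 0.0 {b!r} 0.0 0.0 0.0 {c!r}" time={float(t)!r}\n'
            )
            for j in range(traj.n_atoms):
                x, y, z = (float(v) for v in traj.positions[k, j])
                fh.write(f"{symbol[str(top.role[j])]} {x!r} {y!r} {z!r}\n")
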