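"""File I/O: structures (PDB/mmCIF via gemmi), trajectories (XTC/DCD/multi-
model PDB via MDAnalysis plus a documented plain-text fallback), ground-truth
tables and TSV reports.

Plain fallback trajectory format (one file, whitespace-separated)::

    # helixgate-traj 1
    # natoms <n> nframes <m> frame_spacing_ps <dt>
    # atom <chain> <resid> <resname> <name> <element> <entity> <formal_charge>
    ...  (natoms atom lines)
    # frame <k> time_ps <t>
    x y z        (natoms coordinate lines per frame, fixed atom order)

Coordinates are in Å with 6 decimals; round-trips are bit-identical at that
precision.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Topology, Trajectory, classify_entity
from .errors import FileFormatError, TrajectoryError
from .structcomp import StructureModel

logger = logging.getLogger("helixgate")

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_trajectory_plain",
    "read_trajectory_plain",
    "write_trajectory_pdb",
    "write_ground_truth",
    "read_ground_truth",
    "write_twist_map",
    "write_integrated_deviation",
    "write_engagement_series",
]


# ---------------------------------------------------------------------------
# structures


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Altloc policy: blank or 'A' locations are retained; all others are
    dropped with a logged warning.  Parse failures raise FileFormatError.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileFormatError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FileFormatError(f"could not parse structure {path}: {exc}") from exc
    if len(st) == 0:
        raise FileFormatError(f"structure {path} contains no models")
    st.setup_entities()
    model = st[0]

    chain, resid, icode, resname, atom_name, element, coords = [], [], [], [], [], [], []
    dropped_altloc = 0
    for ch in model:
        for res in ch:
            for atom in res:
                if atom.altloc not in ("", "A", "\0"):
                    dropped_altloc += 1
                    continue
                chain.append(ch.name)
                resid.append(res.seqid.num)
                icode.append((res.seqid.icode or "").strip())
                resname.append(res.name)
                atom_name.append(atom.name)
                element.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if dropped_altloc:
        logger.warning(
            "%s: dropped %d alternate-location atoms (kept altloc A)", path, dropped_altloc
        )
    if not chain:
        raise FileFormatError(f"structure {path} contains no atoms")
    return StructureModel(
        chain=chain,
        resid=resid,
        icode=icode,
        resname=resname,
        atom_name=atom_name,
        element=element,
        coords=coords,
        source=str(path),
    )


# ---------------------------------------------------------------------------
# trajectories


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    try:
        elements = [str(e) for e in atoms.elements]
    except Exception:  # noqa: BLE001 - MDAnalysis guesses may be missing
        elements = [str(n)[0] for n in atoms.names]
    try:
        chains = [str(s) for s in atoms.chainIDs]
    except Exception:  # noqa: BLE001
        chains = [str(s) for s in atoms.segids]
    resnames = [str(r) for r in atoms.resnames]
    return Topology(
        chain=chains,
        resid=atoms.resids,
        resname=resnames,
        atom_name=[str(n) for n in atoms.names],
        element=elements,
        entity=[classify_entity(r) for r in resnames],
    )


def read_trajectory(
    coord_path: str | Path,
    topology_path: str | Path | None = None,
    frame_spacing: float | None = None,
) -> Trajectory:
    """Read a trajectory (XTC/DCD with a topology file, multi-model PDB, or
    the plain fallback format) into a Trajectory.

    ``frame_spacing`` (ps) overrides or supplies the frame time spacing when
    the file carries none.
    """
    coord_path = Path(coord_path)
    if not coord_path.exists():
        raise FileFormatError(f"trajectory file not found: {coord_path}")
    suffix = coord_path.suffix.lower()
    if suffix in (".traj", ".dat", ".txt"):
        traj = read_trajectory_plain(coord_path)
        if frame_spacing is not None:
            traj.frame_times = np.arange(traj.n_frames) * frame_spacing
        return traj

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if suffix in (".xtc", ".dcd", ".trr"):
                if topology_path is None:
                    raise FileFormatError(
                        f"binary trajectory {coord_path} requires a topology file"
                    )
                u = mda.Universe(str(topology_path), str(coord_path))
            else:
                u = mda.Universe(str(coord_path), str(coord_path))
        except FileFormatError:
            raise
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            raise FileFormatError(f"could not parse trajectory {coord_path}: {exc}") from exc

        top = _topology_from_universe(u)
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
    if coords.shape[1] != top.n_atoms:
        raise TrajectoryError(
            f"trajectory has {coords.shape[1]} atoms but topology has {top.n_atoms}"
        )
    n_frames = coords.shape[0]
    if frame_spacing is not None:
        times = np.arange(n_frames) * frame_spacing
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            times = np.array([ts.time for ts in u.trajectory], dtype=np.float64)
        if n_frames > 1 and np.allclose(np.diff(times), 0):
            times = np.arange(n_frames, dtype=np.float64)
    return Trajectory(topology=top, coords=coords, frame_times=times)


def write_trajectory_plain(traj: Trajectory, path: str | Path) -> None:
    """Write the documented plain fallback format (see module docstring)."""
    path = Path(path)
    dt = traj.frame_spacing
    with path.open("w") as fh:
        fh.write("# helixgate-traj 1\n")
        fh.write(
            f"# natoms {traj.n_atoms} nframes {traj.n_frames} "
            f"frame_spacing_ps {0.0 if np.isnan(dt) else dt:g}\n"
        )
        t = traj.topology
        for i in range(traj.n_atoms):
            fh.write(
                f"# atom {t.chain[i]} {t.resid[i]} {t.resname[i]} {t.atom_name[i]} "
                f"{t.element[i]} {t.entity[i]} {t.formal_charge[i]}\n"
            )
        for f in range(traj.n_frames):
            fh.write(f"# frame {f} time_ps {traj.frame_times[f]:.6f}\n")
            for xyz in traj.coords[f]:
                fh.write(f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_trajectory_plain(path: str | Path) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# helixgate-traj"):
        raise FileFormatError(f"{path} is not a helixgate plain trajectory (bad header)")
    try:
        header = lines[1].split()
        natoms, nframes = int(header[2]), int(header[4])
    except (IndexError, ValueError) as exc:
        raise FileFormatError(f"{path}: malformed size header at line 2") from exc

    chain, resid, resname, name, element, entity, charge = [], [], [], [], [], [], []
    ln = 2
    for _ in range(natoms):
        parts = lines[ln].split()
        if parts[:2] != ["#", "atom"]:
            raise FileFormatError(f"{path}: expected atom line at line {ln + 1}")
        chain.append(parts[2])
        resid.append(int(parts[3]))
        resname.append(parts[4])
        name.append(parts[5])
        element.append(parts[6])
        entity.append(parts[7])
        charge.append(int(parts[8]))
        ln += 1
    top = Topology(
        chain=chain, resid=resid, resname=resname, atom_name=name,
        element=element, entity=entity, formal_charge=charge,
    )
    coords = np.empty((nframes, natoms, 3))
    times = np.empty(nframes)
    for f in range(nframes):
        parts = lines[ln].split()
        if parts[:2] != ["#", "frame"]:
            raise FileFormatError(f"{path}: expected frame header at line {ln + 1}")
        times[f] = float(parts[4])
        ln += 1
        for a in range(natoms):
            try:
                coords[f, a] = [float(v) for v in lines[ln].split()[:3]]
            except (IndexError, ValueError) as exc:
                raise FileFormatError(
                    f"{path}: bad coordinate line {ln + 1} (frame {f}, atom {a})"
                ) from exc
            ln += 1
    return Trajectory(topology=top, coords=coords, frame_times=times)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    path = Path(path)
    t = traj.topology
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(traj.n_atoms):
                record = "HETATM" if t.entity[i] in ("ligand", "water") else "ATOM  "
                x, y, z = traj.coords[f, i]
                fh.write(
                    f"{record}{i + 1:5d} {str(t.atom_name[i])[:4]:^4s}"
                    f"{str(t.resname[i])[:3]:>4s} {str(t.chain[i])[:1]}"
                    f"{int(t.resid[i]):4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {str(t.element[i])[:2]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# ground truth and reports


def write_ground_truth(traj: Trajectory, path: str | Path) -> None:
    """Serialise per-frame ground-truth arrays as TSV (one column per key)."""
    path = Path(path)
    cols: dict[str, object] = {}
    for key, val in traj.ground_truth.items():
        arr = np.asarray(val)
        if arr.ndim == 1 and len(arr) == traj.n_frames:
            cols[key] = arr
        elif arr.ndim == 2 and arr.shape[0] == traj.n_frames:
            for j in range(arr.shape[1]):
                cols[f"{key}[{j}]"] = arr[:, j]
        # scalar/structural entries are stored in the header comment
    df = pd.DataFrame(cols)
    df.insert(0, "frame", np.arange(traj.n_frames))
    df.insert(1, "time_ps", traj.frame_times)
    with Path(path).open("w") as fh:
        scalars = {
            k: np.asarray(v).tolist()
            for k, v in traj.ground_truth.items()
            if np.asarray(v).ndim == 0
            or (np.asarray(v).ndim == 1 and len(np.asarray(v)) != traj.n_frames)
        }
        fh.write(f"# ground-truth scalars: {scalars}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_twist_map(tmap, path: str | Path) -> None:
    """Long-format TSV: residue, time_ps, theta, delta_theta."""
    res = np.repeat(tmap.residue_ids, len(tmap.frame_times))
    times = np.tile(tmap.frame_times, len(tmap.residue_ids))
    pd.DataFrame(
        {
            "residue": res,
            "time_ps": times,
            "theta_deg": tmap.theta.ravel(),
            "delta_theta_deg": tmap.delta_theta.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_integrated_deviation(integ, path: str | Path) -> None:
    pd.DataFrame(
        {"residue": integ.residue_ids, "integrated_deviation_deg_us": integ.value}
    ).to_csv(path, sep="\t", index=False)


def write_engagement_series(series, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_ps": series.frame_times,
            "hbond_count": series.hbond_count,
            "min_distance_A": series.min_distance,
        }
    ).to_csv(path, sep="\t", index=False)
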