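"""Coarse-grained bead models and their geometry.

The structural currency of the pipeline is a one-bead-per-residue model
(beads at CA positions, uniform unit mass) carrying two label columns:
a *protomer* id (chain A or B for a dimer) and a *domain* id (e.g.
``RB1B2-A``, ``CC-A``, ``LINKER-A``, ``PHDBR-A`` and the B counterparts).
Domain metadata — residue ranges and a rigid/flexible flag — lives in a
sidecar table rather than abused PDB fields, because the PDB format has
no domain column.

Conventions: all lengths in Å; residue ranges are 0-based, half-open;
consecutive beads within a protomer are pseudo-bonded at an ideal CA–CA
distance of 3.8 Å.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

IDEAL_BOND = 3.8
#: a bonded bead pair further apart than this breaks topological validity
BOND_VALID_MAX = 4.5


class LabelingError(ValueError):
    """Sidecar domain ranges do not cover / match the model."""


class FormatError(ValueError):
    """Malformed bead-PDB or sidecar input."""


class SelectionError(ValueError):
    """A bead selector matched nothing."""


@dataclass(frozen=True)
class DomainDefinition:
    """A named residue range within one protomer.

    ``start``/``end`` are 0-based half-open residue indices local to the
    protomer. ``rigid`` marks domains treated as rigid bodies (folded
    modules) as opposed to flexible linkers.
    """

    name: str
    chain: str
    start: int
    end: int
    rigid: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"empty residue range for domain {self.name!r}: "
                f"[{self.start}, {self.end})"
            )

    @property
    def n_residues(self) -> int:
        return self.end - self.start


@dataclass
class BeadModel:
    """One-bead-per-residue model of a (dimeric) multidomain protein.

    Attributes
    ----------
    coords : (n, 3) float array, Å
    protomer_id : (n,) array of str — chain label per bead ('A'/'B').
    domain_id : (n,) array of str — domain label per bead.
    masses : (n,) float array, uniform 1.0 unless overridden.
    bonds : (m, 2) int array — consecutive-bead pseudo-bonds within each
        protomer (indices into ``coords``).
    domains : list of DomainDefinition in file order.
    """

    coords: np.ndarray
    protomer_id: np.ndarray
    domain_id: np.ndarray
    domains: list[DomainDefinition] = field(default_factory=list)
    masses: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    bonds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.protomer_id = np.asarray(self.protomer_id, dtype=object)
        self.domain_id = np.asarray(self.domain_id, dtype=object)
        if len(self.protomer_id) != n or len(self.domain_id) != n:
            raise FormatError("label arrays must match the number of beads")
        if self.masses is None:
            self.masses = np.ones(n)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.bonds is None:
            self.bonds = _chain_bonds(self.protomer_id)
        else:
            self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.coords)

    def copy(self) -> "BeadModel":
        return BeadModel(
            coords=self.coords.copy(),
            protomer_id=self.protomer_id.copy(),
            domain_id=self.domain_id.copy(),
            domains=list(self.domains),
            masses=self.masses.copy(),
            metadata=dict(self.metadata),
            bonds=self.bonds.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "BeadModel":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(out.coords) != self.n_beads:
            raise FormatError("coordinate replacement changes bead count")
        return out

    def select(self, domain: str | None = None, protomer: str | None = None) -> np.ndarray:
        """Indices of beads matching domain and/or protomer labels."""
        mask = np.ones(self.n_beads, dtype=bool)
        if domain is not None:
            mask &= np.asarray([d == domain for d in self.domain_id])
        if protomer is not None:
            mask &= np.asarray([p == protomer for p in self.protomer_id])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(
                f"no beads match domain={domain!r}, protomer={protomer!r}"
            )
        return idx

    def bond_lengths(self) -> np.ndarray:
        d = self.coords[self.bonds[:, 0]] - self.coords[self.bonds[:, 1]]
        return np.linalg.norm(d, axis=1)

    def is_topologically_valid(self, max_bond: float = BOND_VALID_MAX) -> bool:
        """True when every pseudo-bond is shorter than ``max_bond`` Å."""
        if len(self.bonds) == 0:
            return True
        return bool(self.bond_lengths().max() < max_bond)

    def validate_domains(self) -> None:
        """Check that the domain partition covers all beads exactly once."""
        for chain in sorted(set(self.protomer_id)):
            idx = np.flatnonzero(self.protomer_id == chain)
            defs = sorted(
                (d for d in self.domains if d.chain == chain),
                key=lambda d: d.start,
            )
            covered = 0
            prev_end = None
            for d in defs:
                if prev_end is not None and d.start < prev_end:
                    raise LabelingError(
                        f"overlapping domain ranges on chain {chain}"
                    )
                covered += d.n_residues
                prev_end = d.end
            if covered != idx.size:
                raise LabelingError(
                    f"domains cover {covered} of {idx.size} residues on "
                    f"chain {chain}"
                )


def _chain_bonds(protomer_id: np.ndarray) -> np.ndarray:
    """Consecutive-bead bonds, broken at protomer boundaries."""
    pid = np.asarray(protomer_id)
    n = len(pid)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    i = np.arange(n - 1)
    same = pid[:-1] == pid[1:]
    return np.stack([i[same], i[same] + 1], axis=1)


# ----------------------------------------------------------------------
# geometry


def center_of_mass(
    model: BeadModel,
    domain: str | None = None,
    protomer: str | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of the selected beads (Å)."""
    idx = model.select(domain=domain, protomer=protomer)
    w = model.masses[idx]
    return (model.coords[idx] * w[:, None]).sum(axis=0) / w.sum()


def radius_of_gyration(model: BeadModel, indices: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance from the centre of mass (Å)."""
    if indices is None:
        coords, w = model.coords, model.masses
    else:
        coords, w = model.coords[indices], model.masses[indices]
    if len(coords) < 2:
        raise SelectionError("radius of gyration needs at least 2 beads")
    com = (coords * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


# ----------------------------------------------------------------------
# IO: CA-only PDB + sidecar domain table


def read_sidecar(path_or_buf) -> list[DomainDefinition]:
    """Read a domain sidecar (CSV: chain, start, end, domain, rigid)."""
    tbl = pd.read_csv(path_or_buf, comment="#", skipinitialspace=True)
    required = {"chain", "start", "end", "domain", "rigid"}
    if not required.issubset(tbl.columns):
        raise FormatError(
            f"sidecar must have columns {sorted(required)}, got {list(tbl.columns)}"
        )
    out = []
    for row in tbl.itertuples():
        rigid = str(row.rigid).strip().lower() in {"1", "true", "yes", "rigid"}
        out.append(
            DomainDefinition(
                name=str(row.domain),
                chain=str(row.chain).strip(),
                start=int(row.start),
                end=int(row.end),
                rigid=rigid,
            )
        )
    return out


def write_sidecar(domains: list[DomainDefinition], path) -> None:
    tbl = pd.DataFrame(
        {
            "chain": [d.chain for d in domains],
            "start": [d.start for d in domains],
            "end": [d.end for d in domains],
            "domain": [d.name for d in domains],
            "rigid": [int(d.rigid) for d in domains],
        }
    )
    tbl.to_csv(path, index=False)


def read_bead_pdb(path, sidecar_path) -> BeadModel:
    """Read a CA-only PDB plus its domain sidecar into a BeadModel.

    Residue numbering must be strictly increasing within each chain; every
    residue must fall inside exactly one sidecar range for its chain.
    """
    domains = read_sidecar(sidecar_path)
    coords, chains, resids = [], [], []
    if hasattr(path, "read"):
        fh = io.StringIO(path.read())
    else:
        fh = open(path)
    with fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            name = line[12:16].strip()
            if name != "CA":
                continue
            chains.append(line[21].strip() or "A")
            try:
                resids.append(int(line[22:26]))
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            except ValueError as exc:
                raise FormatError(f"unparsable ATOM record: {line!r}") from exc
    if not coords:
        raise FormatError("no CA ATOM records found")
    coords = np.asarray(coords)
    chains = np.asarray(chains, dtype=object)
    resids = np.asarray(resids)

    domain_id = np.empty(len(coords), dtype=object)
    for chain in sorted(set(chains)):
        mask = chains == chain
        r = resids[mask]
        if np.any(np.diff(r) <= 0):
            raise FormatError(f"non-monotone residue numbering in chain {chain}")
        local = r - r.min()  # residue numbers are 1-based in the file
        defs = [d for d in domains if d.chain == chain]
        lab = np.full(mask.sum(), None, dtype=object)
        for d in defs:
            sel = (local >= d.start) & (local < d.end)
            lab[sel] = d.name
        if any(v is None for v in lab):
            missing = int(sum(v is None for v in lab))
            raise LabelingError(
                f"{missing} residues in chain {chain} not covered by sidecar"
            )
        domain_id[mask] = lab

    model = BeadModel(
        coords=coords, protomer_id=chains, domain_id=domain_id, domains=domains
    )
    model.validate_domains()
    return model


def write_bead_pdb(model: BeadModel, path, sidecar_path=None) -> None:
    """Write a CA-only PDB (chains per protomer) and optional sidecar."""
    lines = []
    serial = 0
    for chain in sorted(set(model.protomer_id)):
        idx = np.flatnonzero(model.protomer_id == chain)
        for local, i in enumerate(idx, start=1):
            serial += 1
            x, y, z = model.coords[i]
            lines.append(
                f"ATOM  {serial % 100000:5d}  CA  ALA {chain}{local:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if sidecar_path is not None:
        write_sidecar(model.domains, sidecar_path)


def transform(model: BeadModel, rotation: np.ndarray, translation: np.ndarray) -> BeadModel:
    """Apply a rigid transformation to the whole model."""
    R = np.asarray(rotation, dtype=float).reshape(3, 3)
    t = np.asarray(translation, dtype=float).reshape(3)
    return model.with_coords(model.coords @ R.T + t)
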