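"""Seven-transmembrane bundle model with per-helix rigid-body variables.

Each helix carries six scalar placement variables defined in a bundle frame
frozen at construction time: radial distance and azimuth of the helix center
in the membrane plane, offset along the bundle axis, tilt angle and tilt
azimuth of the helix axis, and axial spin.  Placement decomposes as a ZYZ
rotation applied to an immutable helix-local template, so setting variables
is an exact rigid transform and the variables are recoverable from the
coordinates alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import principal_axis, rot_z, tilt_rotation
from .structure import BACKBONE_ATOMS, Structure

# O(i)..O(i+4) distance in an ideal (phi=-57, psi=-47) alpha helix; measured
# once on the generated ideal geometry and frozen here.
IDEAL_O_O_DISTANCE = 6.35


@dataclass(frozen=True)
class HelixRigidVariables:
    """Six rigid-body placement variables of one helix (Angstrom / degrees)."""

    radial: float
    azimuth: float
    z_offset: float
    tilt: float
    tilt_azimuth: float
    spin: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.radial, self.azimuth, self.z_offset, self.tilt, self.tilt_azimuth, self.spin]
        )

    def validate(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"non-finite rigid variable: {self}")


class HelixSegment:
    """View of one helix (contiguous atom block) inside a bundle structure."""

    def __init__(self, helix_id: int, structure: Structure, span: tuple[int, int]):
        self.helix_id = helix_id
        self.structure = structure
        self.span = span

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def residue_ids(self) -> np.ndarray:
        return self.structure.residue_ids()

    @property
    def residues(self) -> list[dict]:
        out = []
        for rid in self.residue_ids:
            mask = self.structure.res_seq == rid
            out.append(
                {
                    "name": str(self.structure.res_names[mask][0]),
                    "seq": int(rid),
                    "atoms": list(self.structure.atom_names[mask]),
                    "elements": list(self.structure.elements[mask]),
                    "coords": self.structure.coords[mask],
                }
            )
        return out

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords

    def backbone_coords(self) -> np.ndarray:
        mask = np.isin(self.structure.atom_names, BACKBONE_ATOMS)
        return self.structure.coords[mask]

    def ca_coords(self) -> np.ndarray:
        return self.structure.coords[self.structure.atom_names == "CA"]

    def center(self) -> np.ndarray:
        return self.structure.coords.mean(axis=0)

    def axis(self) -> np.ndarray:
        """Unit axis via the principal component of the backbone, sign-fixed
        from first to last CA."""
        ax = principal_axis(self.backbone_coords())
        ca = self.ca_coords()
        if np.dot(ax, ca[-1] - ca[0]) < 0:
            ax = -ax
        return ax

    def validate(self) -> None:
        rids = self.residue_ids
        if len(rids) < 6:
            raise ValueError(f"helix {self.helix_id} has {len(rids)} residues; need >= 6")
        first, last = self.span
        expected = np.arange(first, last + 1)
        if not np.array_equal(rids, expected):
            raise ValueError(
                f"helix {self.helix_id}: residue numbering not contiguous over span {self.span}"
            )
        for rid in rids:
            present = set(self.structure.atom_names[self.structure.res_seq == rid])
            missing = [a for a in BACKBONE_ATOMS if a not in present]
            if missing:
                raise ValueError(
                    f"helix {self.helix_id} residue {rid}: missing backbone atom(s) "
                    + ",".join(missing)
                )


class BundleState:
    """A 7TM (or synthetic n-helix) bundle with rigid-body helix variables.

    The bundle frame (origin + orthonormal axes with z along the bundle axis)
    is frozen when the state is first built, so the six variables of each
    helix are well-defined coordinates, not moving targets.
    """

    def __init__(
        self,
        structure: Structure,
        helix_slices: list[slice],
        spans: list[tuple[int, int]],
        frame_origin: np.ndarray | None = None,
        frame_axes: np.ndarray | None = None,
        templates: list[np.ndarray] | None = None,
    ):
        if len(helix_slices) != len(spans):
            raise ValueError("helix_slices and spans must have equal length")
        self.structure = structure
        self.helix_slices = list(helix_slices)
        self.spans = list(spans)
        for seg in self.helices:
            seg.validate()
        if frame_origin is None or frame_axes is None:
            frame_origin = self.bundle_center
            axis = bundle_axis(self) if self.n_helices >= 2 else self.helix(1).axis()
            frame_axes = _frame_from_axis(axis)
        self.frame_origin = np.asarray(frame_origin, dtype=float)
        self.frame_axes = np.asarray(frame_axes, dtype=float)
        if templates is None:
            templates = [None] * self.n_helices
        self._templates = list(templates)
        for i in range(self.n_helices):
            if self._templates[i] is None:
                self._templates[i] = self._build_template(i)

    # ------------------------------------------------------------------ views

    @property
    def n_helices(self) -> int:
        return len(self.helix_slices)

    @property
    def helices(self) -> list[HelixSegment]:
        return [
            HelixSegment(i + 1, self.structure.select(np.r_[sl]), self.spans[i])
            for i, sl in enumerate(self.helix_slices)
        ]

    def helix(self, helix_id: int) -> HelixSegment:
        self._check_helix_id(helix_id)
        sl = self.helix_slices[helix_id - 1]
        return HelixSegment(helix_id, self.structure.select(np.r_[sl]), self.spans[helix_id - 1])

    def helix_coords(self, helix_id: int) -> np.ndarray:
        return self.structure.coords[self.helix_slices[helix_id - 1]]

    def helix_center(self, helix_id: int) -> np.ndarray:
        return self.helix_coords(helix_id).mean(axis=0)

    def helix_residue_count(self, helix_id: int) -> int:
        first, last = self.spans[helix_id - 1]
        return last - first + 1

    @property
    def helix_centers(self) -> np.ndarray:
        return np.array([self.helix_center(i + 1) for i in range(self.n_helices)])

    @property
    def bundle_center(self) -> np.ndarray:
        """Residue-count-weighted mean of the helix geometric centers."""
        w = np.array([self.helix_residue_count(i + 1) for i in range(self.n_helices)], float)
        return (w[:, None] * self.helix_centers).sum(axis=0) / w.sum()

    @property
    def bundle_axis(self) -> np.ndarray:
        return bundle_axis(self)

    @property
    def rigid_vars(self) -> list[HelixRigidVariables]:
        return [self.get_rigid_variables(i + 1) for i in range(self.n_helices)]

    def copy(self) -> "BundleState":
        return BundleState(
            self.structure.copy(),
            self.helix_slices,
            self.spans,
            self.frame_origin.copy(),
            self.frame_axes.copy(),
            [t.copy() for t in self._templates],
        )

    def _check_helix_id(self, helix_id: int) -> None:
        if not (1 <= helix_id <= self.n_helices):
            raise ValueError(f"helix_id {helix_id} out of range 1..{self.n_helices}")

    # --------------------------------------------------- rigid-variable layer

    def _to_frame(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.frame_origin) @ self.frame_axes

    def _from_frame(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.frame_axes.T + self.frame_origin

    def _build_template(self, i: int) -> np.ndarray:
        """Helix-local template: centered, axis along +z, fixed x reference."""
        y = self._to_frame(self.structure.coords[self.helix_slices[i]])
        c = y.mean(axis=0)
        seg = self.helix(i + 1)
        ax = principal_axis(self._to_frame(seg.backbone_coords()) - c)
        ca = self._to_frame(seg.ca_coords()) - c
        if np.dot(ax, ca[-1] - ca[0]) < 0:
            ax = -ax
        ref = y[0] - c
        x = ref - np.dot(ref, ax) * ax
        nx = np.linalg.norm(x)
        if nx < 1e-9:
            x = np.array([1.0, 0.0, 0.0]) - ax[0] * ax
            nx = np.linalg.norm(x)
        x /= nx
        m = np.stack([x, np.cross(ax, x), ax], axis=1)
        return (y - c) @ m

    def get_rigid_variables(self, helix_id: int) -> HelixRigidVariables:
        """Recover the six placement variables from the current coordinates."""
        self._check_helix_id(helix_id)
        i = helix_id - 1
        y = self._to_frame(self.structure.coords[self.helix_slices[i]])
        t = y.mean(axis=0)
        template = self._templates[i]
        # rigid fit template -> y (both centered); exact because the template
        # was built from the same internal geometry
        from .geometry import kabsch

        r, _ = kabsch(template, y - t)
        d = r @ np.array([0.0, 0.0, 1.0])
        tilt = np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0)))
        if tilt > 1e-9:
            tilt_az = np.degrees(np.arctan2(d[1], d[0]))
        else:
            tilt_az = 0.0
        rs = tilt_rotation(tilt, tilt_az).T @ r
        spin = np.degrees(np.arctan2(rs[1, 0], rs[0, 0]))
        return HelixRigidVariables(
            radial=float(np.hypot(t[0], t[1])),
            azimuth=float(np.degrees(np.arctan2(t[1], t[0]))),
            z_offset=float(t[2]),
            tilt=float(tilt),
            tilt_azimuth=float(tilt_az),
            spin=float(spin),
        )

    def place_helix(self, helix_id: int, v: HelixRigidVariables) -> np.ndarray:
        """Coordinates of a helix placed at the given variables (world frame)."""
        self._check_helix_id(helix_id)
        v.validate()
        i = helix_id - 1
        r = tilt_rotation(v.tilt, v.tilt_azimuth) @ rot_z(v.spin)
        az = np.deg2rad(v.azimuth)
        t = np.array([v.radial * np.cos(az), v.radial * np.sin(az), v.z_offset])
        return self._from_frame(self._templates[i] @ r.T + t)


def _frame_from_axis(axis: np.ndarray) -> np.ndarray:
    z = np.asarray(axis, dtype=float)
    z = z / np.linalg.norm(z)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, z)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    x = seed - np.dot(seed, z) * z
    x /= np.linalg.norm(x)
    return np.stack([x, np.cross(z, x), z], axis=1)


# ------------------------------------------------------------------ operations


def extract_helices(structure: Structure, ranges: list[tuple[int, int]]) -> BundleState:
    """Carve helix spans out of a structure, discarding everything else.

    ``ranges`` are inclusive (first, last) residue-number spans, one per
    helix, in helix order.  Rigid variables are initialized from the
    extracted coordinates.
    """
    parts, slices, spans = [], [], []
    offset = 0
    for first, last in ranges:
        mask = (structure.res_seq >= first) & (structure.res_seq <= last)
        part = structure.select(mask)
        present = set(int(r) for r in part.res_seq)
        for rid in range(first, last + 1):
            if rid not in present:
                raise ValueError(f"residue {rid} of span {first}-{last} absent from structure")
        parts.append(part)
        slices.append(slice(offset, offset + len(part)))
        spans.append((first, last))
        offset += len(part)
    return BundleState(Structure.concat(parts), slices, spans)


def set_rigid_variables(
    bundle: BundleState, helix_id: int, v: HelixRigidVariables
) -> BundleState:
    """Return a new bundle with one helix rigidly re-placed at ``v``."""
    new = bundle.copy()
    new.structure.coords[new.helix_slices[helix_id - 1]] = bundle.place_helix(helix_id, v)
    return new


def helix_axis_segments(
    helix: HelixSegment,
    kink_tolerance: float = 1.0,
    ideal_o_o: float = IDEAL_O_O_DISTANCE,
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Split a helix at kinks and return per-segment residue spans and axes.

    A kink is declared between residues where the carbonyl-O(i)->O(i+4)
    distance deviates from the ideal alpha-helical value by more than
    ``kink_tolerance`` (Angstrom).  Segments shorter than 4 residues are
    merged into their neighbor.  Axes are principal components of segment
    backbone atoms, sign-aligned N->C.
    """
    st = helix.structure
    rids = helix.residue_ids
    n = len(rids)
    o_coords = []
    for rid in rids:
        sel = (st.res_seq == rid) & (st.atom_names == "O")
        o_coords.append(st.coords[sel][0])
    o_coords = np.array(o_coords)

    kinks = []
    for i in range(n - 4):
        d = np.linalg.norm(o_coords[i + 4] - o_coords[i])
        if abs(d - ideal_o_o) > kink_tolerance:
            kinks.append(i + 2)  # split near the middle of the anomalous stretch
    # collapse runs of consecutive anomalies into one split point each
    breaks: list[int] = []
    for k in kinks:
        if not breaks or k - breaks[-1] > 2:
            breaks.append(k)
    bounds = [0] + [b for b in breaks if 4 <= b <= n - 4] + [n]
    bounds = sorted(set(bounds))
    # enforce minimum segment length 4
    cleaned = [bounds[0]]
    for b in bounds[1:]:
        if b - cleaned[-1] >= 4 or b == n:
            cleaned.append(b)
    if cleaned[-1] != n:
        cleaned.append(n)
    if n >= 8 and cleaned[-1] - cleaned[-2] < 4 and len(cleaned) > 2:
        cleaned.pop(-2)

    segments = []
    for a, b in zip(cleaned[:-1], cleaned[1:]):
        seg_rids = rids[a:b]
        mask = np.isin(st.res_seq, seg_rids) & np.isin(st.atom_names, BACKBONE_ATOMS)
        coords = st.coords[mask]
        ax = principal_axis(coords)
        ca_mask = np.isin(st.res_seq, seg_rids) & (st.atom_names == "CA")
        ca = st.coords[ca_mask]
        if np.dot(ax, ca[-1] - ca[0]) < 0:
            ax = -ax
        segments.append(((int(seg_rids[0]), int(seg_rids[-1])), ax))
    return segments


def bundle_axis(
    bundle: BundleState,
    cluster_cutoff_deg: float = 30.0,
    exclude_fraction: float = 0.10,
) -> np.ndarray:
    """Residue-count-weighted mean helix direction, outliers excluded.

    Helix axes are sign-aligned (antiparallel helices flipped), then
    single-link clustered at ``cluster_cutoff_deg``; up to
    ``floor(exclude_fraction * n)`` vectors outside the largest cluster are
    dropped before the weighted, normalized sum.
    """
    n = bundle.n_helices
    if n < 2:
        raise ValueError("bundle_axis requires >= 2 helices")
    axes = []
    weights = []
    for i in range(n):
        seg = bundle.helix(i + 1)
        axes.append(seg.axis())
        weights.append(bundle.helix_residue_count(i + 1))
    axes = np.array(axes)
    weights = np.array(weights, dtype=float)
    if np.any(np.linalg.norm(axes, axis=1) < 1e-12):
        raise ValueError("degenerate helix axis")
    # sign-align to the first axis direction (antiparallel topology)
    ref = axes[0]
    for i in range(1, n):
        if np.dot(axes[i], ref) < 0:
            axes[i] = -axes[i]

    # single-link clustering on angular distance
    cut = np.cos(np.deg2rad(cluster_cutoff_deg))
    labels = -np.ones(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in range(n):
                if labels[k] < 0 and np.dot(axes[j], axes[k]) >= cut:
                    labels[k] = current
                    stack.append(k)
        current += 1
    counts = np.bincount(labels)
    main = int(np.argmax(counts))
    max_excluded = int(np.floor(exclude_fraction * n))
    outliers = np.flatnonzero(labels != main)
    if len(outliers) > max_excluded:
        # not allowed to exclude that many: keep everything
        keep = np.arange(n)
    else:
        keep = np.flatnonzero(labels == main)
    v = (weights[keep, None] * axes[keep]).sum(axis=0)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise ValueError("degenerate bundle axis (weighted sum vanished)")
    return v / nv


def membrane_frame(bundle: BundleState) -> tuple[np.ndarray, np.ndarray]:
    """Membrane mid-plane: passes through the bundle center, normal along the
    bundle axis."""
    return bundle.bundle_center, bundle.bundle_axis


def helix_elevations(bundle: BundleState) -> np.ndarray:
    """Signed offsets of helix centers from the membrane mid-plane.

    Residue-weighted sum is zero by construction of the mid-plane.
    """
    point, normal = membrane_frame(bundle)
    return (bundle.helix_centers - point) @ normal
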