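"""First-shell coordination statistics and the shell-resolved PMF.

The potential of mean force of species ``l`` around species ``k`` is
taken from the ratio of first-shell to bulk concentration,

    PMF_kl = -k_B T ln( c_l(shell) / c_l ),
    c_l(shell) = <N_kl> / V_k,   c_l = N_l / V,

with negative values indicating enrichment of ``l`` in ``k``'s first
shell.  The first shell is defined here by a per-species-pair radial
cutoff (by default the first minimum of the pair RDF) and its volume by
the cutoff sphere ``V_k = 4/3 pi r_cut^3``.  Absolute PMFs therefore
carry a pair-wise offset relative to a tessellation-based shell volume;
*differences* between two runs (``delta_pmf``) are far less affected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError
from .geometry import fold, minimum_image
from .system import BoxSpec
from .units import DEFAULT_UNITS, KCAL_PER_KJ, UnitSystem

__all__ = [
    "ShellAssignment",
    "PMFMatrix",
    "resolve_cutoff",
    "first_shell_neighbors",
    "shell_pmf",
    "delta_pmf",
    "pair_rdf",
    "first_rdf_minimum",
]

CutoffSpec = float | Mapping[tuple[str, str], float]


def resolve_cutoff(cutoffs: CutoffSpec, k: str, l: str) -> float:
    if isinstance(cutoffs, (int, float)):
        return float(cutoffs)
    if (k, l) in cutoffs:
        return float(cutoffs[(k, l)])
    if (l, k) in cutoffs:
        return float(cutoffs[(l, k)])
    raise KeyError(f"no cutoff for species pair ({k}, {l})")


@dataclass
class ShellAssignment:
    """First-shell neighbor set of one central residue in one frame."""

    central_id: int
    species: str
    neighbors: list[tuple[int, str]]
    shell_radius: float
    shell_volume: float


def first_shell_neighbors(
    positions: np.ndarray,
    species: Sequence[str],
    box: BoxSpec,
    cutoffs: CutoffSpec,
) -> list[ShellAssignment]:
    """Neighbor sets under the minimum image for one frame.

    With a symmetric cutoff table the relation is symmetric: ``l`` in the
    shell of ``k`` iff ``k`` in the shell of ``l``.  One assignment per
    central residue; the recorded radius/volume are those of the largest
    pair cutoff involving the central species (per-pair radii are applied
    when counting).
    """
    positions = np.asarray(positions, float)
    lengths = box.array
    labels = list(species)
    unique = sorted(set(labels))
    half = box.min_length / 2.0
    for k in unique:
        for l in unique:
            if resolve_cutoff(cutoffs, k, l) >= half:
                raise GeometryError(
                    f"cutoff for ({k},{l}) must be < half box ({half} A)"
                )
    tree = cKDTree(fold(positions, lengths), boxsize=lengths)
    r_global = max(resolve_cutoff(cutoffs, k, l) for k in unique for l in unique)
    pairs = tree.query_pairs(r_global, output_type="ndarray")

    neighbor_lists: dict[int, list[tuple[int, str]]] = {m: [] for m in range(len(labels))}
    if len(pairs):
        d = minimum_image(positions[pairs[:, 1]] - positions[pairs[:, 0]], lengths)
        dist = np.sqrt(np.sum(d * d, axis=1))
        for (i, j), r in zip(pairs, dist):
            rc = resolve_cutoff(cutoffs, labels[i], labels[j])
            if r <= rc:
                neighbor_lists[i].append((int(j), labels[j]))
                neighbor_lists[j].append((int(i), labels[i]))

    out = []
    for m, lab in enumerate(labels):
        rc = max(resolve_cutoff(cutoffs, lab, l) for l in unique)
        out.append(
            ShellAssignment(
                central_id=m,
                species=lab,
                neighbors=sorted(neighbor_lists[m]),
                shell_radius=rc,
                shell_volume=4.0 / 3.0 * np.pi * rc**3,
            )
        )
    return out


@dataclass
class PMFMatrix:
    """Species-by-species shell PMF (kcal/mol) with the underlying counts.

    Depleted entries (no neighbor ever observed) are +inf; writers emit
    them as the string ``+inf`` rather than a numeric value.
    """

    species: tuple[str, ...]
    pmf_kcal: np.ndarray  # (K, K)
    counts: np.ndarray  # mean N_kl
    bulk_concentration: np.ndarray  # c_l per species, 1/A^3

    @property
    def pmf_kj(self) -> np.ndarray:
        return self.pmf_kcal / KCAL_PER_KJ

    def to_frame(self, unit: str = "kcal") -> pd.DataFrame:
        mat = self.pmf_kcal if unit == "kcal" else self.pmf_kj
        return pd.DataFrame(mat, index=list(self.species), columns=list(self.species))

    def write(self, path, unit: str = "kcal") -> None:
        df = self.to_frame(unit).replace(np.inf, "+inf")
        df.to_csv(path, sep="\t")


def shell_pmf(
    assignments_per_frame: Iterable[Sequence[ShellAssignment]],
    bulk_counts: Mapping[str, int],
    volume: float,
    temperature: float,
    cutoffs: CutoffSpec | None = None,
    units: UnitSystem = DEFAULT_UNITS,
) -> PMFMatrix:
    """Trajectory-averaged shell PMF matrix.

    ``assignments_per_frame`` iterates frames, each a sequence of
    :class:`ShellAssignment`.  ``bulk_counts`` maps species to the total
    number of its residues (assumed constant over the analysed frames).
    The shell volume of pair (k, l) is the cutoff sphere; when ``cutoffs``
    is None the radius recorded in the assignments is used for all pairs.
    """
    species = sorted(bulk_counts)
    index = {s: k for k, s in enumerate(species)}
    K = len(species)
    sum_counts = np.zeros((K, K))
    n_centrals = np.zeros(K)
    shell_volume_of: dict[str, float] = {}
    n_frames = 0
    for frame in assignments_per_frame:
        n_frames += 1
        for a in frame:
            k = index[a.species]
            n_centrals[k] += 1
            if a.shell_volume <= 0:
                raise GeometryError("shell volume must be positive")
            shell_volume_of.setdefault(a.species, a.shell_volume)
            for _, lab in a.neighbors:
                sum_counts[k, index[lab]] += 1
    if n_frames == 0:
        raise ValueError("no frames supplied")
    if volume <= 0:
        raise GeometryError("volume must be positive")

    kT = units.kT(temperature)
    pmf = np.full((K, K), np.inf)
    mean_counts = np.zeros((K, K))
    c_bulk = np.array([bulk_counts[s] / volume for s in species])
    for ki, k in enumerate(species):
        if n_centrals[ki] == 0:
            continue
        for li, l in enumerate(species):
            n_kl = sum_counts[ki, li] / n_centrals[ki]
            mean_counts[ki, li] = n_kl
            if cutoffs is not None:
                rc = resolve_cutoff(cutoffs, k, l)
                v_shell = 4.0 / 3.0 * np.pi * rc**3
            else:
                v_shell = shell_volume_of.get(k, 0.0)
            if v_shell <= 0:
                raise GeometryError("shell volume must be positive")
            if n_kl > 0:
                c_shell = n_kl / v_shell
                pmf[ki, li] = -kT * np.log(c_shell / c_bulk[li])
    return PMFMatrix(
        species=tuple(species),
        pmf_kcal=pmf,
        counts=mean_counts,
        bulk_concentration=c_bulk,
    )


def delta_pmf(matrix_a: PMFMatrix, matrix_b: PMFMatrix) -> PMFMatrix:
    """Entrywise PMF difference a - b (antisymmetric under swap)."""
    if matrix_a.species != matrix_b.species:
        raise ValueError(
            f"species sets differ: {matrix_a.species} vs {matrix_b.species}"
        )
    return PMFMatrix(
        species=matrix_a.species,
        pmf_kcal=matrix_a.pmf_kcal - matrix_b.pmf_kcal,
        counts=matrix_a.counts - matrix_b.counts,
        bulk_concentration=matrix_a.bulk_concentration,
    )


# ---------------------------------------------------------------------------
# RDF helper for choosing cutoffs
# ---------------------------------------------------------------------------


def pair_rdf(
    frames: np.ndarray,
    species: Sequence[str],
    box: BoxSpec,
    pair: tuple[str, str],
    r_max: float,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) of one species pair.

    ``frames`` is (F, M, 3) folded residue centers with fixed species
    labels.  Returns bin centers and g.
    """
    frames = np.asarray(frames, float)
    lengths = box.array
    if r_max >= box.min_length / 2.0:
        raise GeometryError("r_max must be < half box")
    labels = np.asarray(list(species))
    sel_k = np.nonzero(labels == pair[0])[0]
    sel_l = np.nonzero(labels == pair[1])[0]
    if len(sel_k) == 0 or len(sel_l) == 0:
        raise ValueError(f"no residues for pair {pair}")
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    same = pair[0] == pair[1]
    for frame in frames:
        d = minimum_image(frame[sel_l][None, :, :] - frame[sel_k][:, None, :], lengths)
        r = np.sqrt(np.sum(d * d, axis=-1))
        if same:
            iu = np.triu_indices(len(sel_k), k=1)
            r = r[iu]
        else:
            r = r.ravel()
        hist += np.histogram(r, bins=edges)[0]
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_pairs = len(sel_k) * (len(sel_k) - 1) / 2 if same else len(sel_k) * len(sel_l)
    rho_pairs = n_pairs / box.volume
    g = hist / (len(frames) * rho_pairs * shell_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, g


def first_rdf_minimum(r: np.ndarray, g: np.ndarray, smooth: int = 3) -> float:
    """First minimum of g(r) after its first peak (shell-cutoff default)."""
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        g = np.convolve(g, kernel, mode="same")
    peak = int(np.argmax(g))
    for i in range(peak + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] <= g[i + 1]:
            return float(r[i])
    return float(r[-1])
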