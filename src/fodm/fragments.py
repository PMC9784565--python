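"""Fragment-level scoring and In/Out conformer comparison.

A fragment (typically a transmembrane helix) is scored by restricting the
chain-level T and O profiles to its residues, renormalizing both, rebuilding
the uniform reference over the fragment, and recomputing RD and K on the
restricted profiles. This keeps fragment statuses comparable across a chain:
the theoretical expectation stays the one Gaussian fitted to the whole
molecule, only read off over the fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    FodStatus,
    HydroProfile,
    fit_k,
    kl_divergence,
    rd,
    uniform_profile,
)
from .errors import InputError
from .structure_io import FragmentSpec, ResId, ResidueRecord

__all__ = [
    "FragmentStatusRow",
    "ComparisonRow",
    "restrict_profile",
    "fragment_status",
    "residue_set_status",
    "deficit_excess",
    "compare_states",
    "contact_residues",
]


@dataclass
class FragmentStatusRow:
    fragment: FragmentSpec
    status: FodStatus


@dataclass
class ComparisonRow:
    """Per-fragment In-vs-Out deltas; ``changed`` flags |ΔK| at or above the
    threshold (default one K grid step, mirroring how status changes are
    conventionally bolded in fragment tables)."""

    label: str
    status_out: FodStatus | None
    status_in: FodStatus | None
    delta_rd: float | None
    delta_k: float | None
    changed: bool


def restrict_profile(profile: HydroProfile, residue_ids: Iterable[ResId]) -> HydroProfile:
    """Select the given residues and renormalize to sum 1."""
    wanted = set(residue_ids)
    if not wanted:
        raise InputError("empty residue selection")
    mask = np.array([rid in wanted for rid in profile.index])
    if not mask.any():
        raise InputError("selection does not intersect the profile index")
    vals = profile.values[mask]
    total = vals.sum()
    if total <= 0:
        raise InputError("selection has zero total mass; cannot renormalize")
    index = tuple(rid for rid, m in zip(profile.index, mask) if m)
    return HydroProfile(profile.kind, vals / total, index)


def _ids_in_range(index: Sequence[ResId], start: int, end: int) -> list[ResId]:
    return [rid for rid in index if start <= rid[1] <= end]


def fragment_status(
    t: HydroProfile,
    o: HydroProfile,
    fragment: FragmentSpec,
    grid: tuple[float, float, float] = (0.0, 10.0, 0.1),
    t_max: float | None = None,
) -> FodStatus:
    """Score one fragment from the chain-level T and O profiles.

    K is fitted on the restricted profiles with the fragment-local T maximum
    (pass ``t_max`` to use a global maximum instead).
    """
    ids = _ids_in_range(t.index, fragment.start, fragment.end)
    if len(ids) < 2:
        raise InputError(
            f"fragment {fragment.label!r} ({fragment.start}-{fragment.end}) maps to "
            f"{len(ids)} residues; need at least 2"
        )
    return _status_for_ids(t, o, ids, grid, t_max)


def _status_for_ids(t, o, ids, grid, t_max=None) -> FodStatus:
    t_f = restrict_profile(t, ids)
    o_f = restrict_profile(o, ids)
    r_f = uniform_profile(len(ids), t_f.index)
    rd_val = rd(o_f, t_f, r_f)
    k_star, curve = fit_k(o_f, t_f, grid=grid, t_max=t_max)
    return FodStatus(
        rd=rd_val,
        k=k_star,
        dkl_ot=kl_divergence(o_f, t_f),
        dkl_or=kl_divergence(o_f, r_f),
        dkl_om_at_k=float(curve[:, 1].min()),
        n_residues=len(ids),
    )


def residue_set_status(
    t: HydroProfile,
    o: HydroProfile,
    residues: Iterable[int],
    window: int = 0,
    grid: tuple[float, float, float] = (0.0, 10.0, 0.1),
) -> FodStatus:
    """Score an arbitrary residue set, optionally widened by ±window in
    author numbering (window 0 scores the set itself). Used e.g. for
    ion-contact residues and their sequence neighbourhood."""
    base = set(residues)
    if not base:
        raise InputError("empty residue set")
    expanded = set()
    for a in base:
        expanded.update(range(a - window, a + window + 1))
    ids = [rid for rid in t.index if rid[1] in expanded]
    if len(ids) < 2:
        raise InputError("residue set maps to fewer than 2 present residues")
    return _status_for_ids(t, o, ids, grid)


def deficit_excess(
    t: HydroProfile, o: HydroProfile, threshold: float = 0.0
) -> list[str]:
    """Label each residue: 'deficit' where expectation exceeds observation
    (T−O > threshold, cavity-lining positions), 'excess' where observation
    exceeds expectation (membrane-contacting surface), else 'concordant'."""
    if len(t) != len(o):
        raise InputError("profile length mismatch")
    diff = t.values - o.values
    return [
        "deficit" if d > threshold else ("excess" if -d > threshold else "concordant")
        for d in diff
    ]


def compare_states(
    out_rows: Sequence[FragmentStatusRow],
    in_rows: Sequence[FragmentStatusRow],
    k_threshold: float = 0.1,
) -> tuple[list[ComparisonRow], dict[str, float]]:
    """Pair Out- and In-form fragment tables by label and report deltas.

    Fragments present in only one form are emitted as unpaired rows with
    null deltas, never dropped. Returns the rows plus per-form totals
    (ΣRD and ΣK over each form's scored fragments).
    """
    if not out_rows and not in_rows:
        raise InputError("both fragment tables are empty")
    out_by = {r.fragment.label: r for r in out_rows}
    in_by = {r.fragment.label: r for r in in_rows}
    labels = list(dict.fromkeys([r.fragment.label for r in out_rows]
                                + [r.fragment.label for r in in_rows]))
    rows: list[ComparisonRow] = []
    for label in labels:
        so = out_by.get(label)
        si = in_by.get(label)
        if so is not None and si is not None:
            d_rd = so.status.rd - si.status.rd
            d_k = so.status.k - si.status.k
            rows.append(ComparisonRow(
                label, so.status, si.status, d_rd, d_k,
                changed=abs(d_k) >= k_threshold - 1e-12,
            ))
        else:
            rows.append(ComparisonRow(
                label,
                so.status if so else None,
                si.status if si else None,
                None, None, changed=False,
            ))
    totals = {
        "sum_rd_out": float(sum(r.status.rd for r in out_rows)),
        "sum_k_out": float(sum(r.status.k for r in out_rows)),
        "sum_rd_in": float(sum(r.status.rd for r in in_rows)),
        "sum_k_in": float(sum(r.status.k for r in in_rows)),
    }
    return rows, totals


def contact_residues(
    residues: Sequence[ResidueRecord],
    het_coords: np.ndarray,
    cutoff: float = 3.5,
) -> list[int]:
    """Author numbers of residues with any heavy atom within ``cutoff`` Å of
    the given HET atom coordinates (e.g. a bound Fe²⁺ or K⁺ ion)."""
    het = np.asarray(het_coords, float).reshape(-1, 3)
    found: list[int] = []
    for res in residues:
        xyz = np.array([[a[1], a[2], a[3]] for a in res.atoms])
        d2 = ((xyz[:, None, :] - het[None, :, :]) ** 2).sum(axis=2)
        if (d2 <= cutoff**2).any():
            found.append(res.auth_seq)
    return found
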