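"""Run orchestration: configuration, output bundles, and In/Out comparison.

A *run* takes one structure (a PDB/mmCIF file, an accession to fetch, or a
previously written effective-atom cloud TSV), computes the chain status and
optional per-fragment statuses, and writes a deterministic bundle of text
outputs: per-residue profile table, fragment status table, JSON summary,
a parameter log, and an optional profile plot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core, fragments, structure_io
from .errors import InputError

__all__ = ["RunConfig", "RunBundle", "run_analysis", "compare_runs"]

_FRAGMENT_COLUMNS = [
    "form", "tm_label", "start", "end", "rd", "k", "dkl_ot", "dkl_or", "n_residues",
]


@dataclass
class RunConfig:
    """Everything a run depends on; all defaults are logged for provenance."""

    pdb: str  # path to a PDB/mmCIF/cloud-TSV file, or a 4-char accession
    chain: str = "A"
    out_dir: str | Path = "fodm_out"
    scale: str | Path | None = None  # None = packaged default scale
    fragments: str | Path | None = None
    cutoff: float = 9.0
    pad: float = 0.0
    k_grid: tuple[float, float, float] = (0.0, 10.0, 0.1)
    model_index: int = 0
    side_chain_only: bool = False
    offline: bool = False
    cache_dir: str | Path = "pdb_cache"
    plot: bool = False
    label: str | None = None  # form label in tables; defaults to the input name


@dataclass
class RunBundle:
    """Paths and in-memory results of one run."""

    out_dir: Path
    summary: dict
    result: core.ChainResult
    fragment_rows: list[fragments.FragmentStatusRow] = field(default_factory=list)

    @property
    def summary_path(self) -> Path:
        return self.out_dir / "summary.json"


def _load_cloud(config: RunConfig) -> structure_io.EffectiveAtomCloud:
    src = str(config.pdb)
    path = Path(src)
    if path.exists():
        head = path.read_text().split("\n", 1)[0]
        if head.startswith("chain\tauth_seq"):
            return structure_io.EffectiveAtomCloud.from_tsv(path)
        text = path.read_text()
    elif len(src.strip()) == 4:
        text = structure_io.fetch_pdb(src, config.cache_dir, offline=config.offline)
    else:
        raise InputError(f"input {src!r} is neither an existing file nor an accession")
    scale = (structure_io.load_scale(config.scale) if config.scale
             else structure_io.default_scale())
    residues = structure_io.parse_structure(text, config.chain, config.model_index)
    return structure_io.compute_effective_atoms(
        residues, scale, side_chain_only=config.side_chain_only
    )


def run_analysis(config: RunConfig) -> RunBundle:
    """Execute the pipeline and write the output bundle under
    ``config.out_dir``. Reruns with the same config are byte-identical."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("fodm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        root.info("config: %s", json.dumps(dataclasses.asdict(config), default=str,
                                           sort_keys=True))
        cloud = _load_cloud(config)
        fod_config = core.FodConfig(cutoff=config.cutoff, pad=config.pad,
                                    k_grid=tuple(config.k_grid))
        result = core.chain_status(cloud, fod_config)
        label = config.label or Path(str(config.pdb)).stem

        _write_profiles(out_dir / "profiles.tsv", cloud, result)

        frag_rows: list[fragments.FragmentStatusRow] = []
        if config.fragments:
            specs = structure_io.load_fragments(config.fragments)
            for spec in specs:
                status = fragments.fragment_status(
                    result.t, result.o, spec, grid=tuple(config.k_grid)
                )
                frag_rows.append(fragments.FragmentStatusRow(spec, status))
            _write_fragment_table(out_dir / "fragment_status.tsv", label, frag_rows)

        summary = {
            "label": label,
            "rd": result.status.rd,
            "k": result.status.k,
            "dkl_ot": result.status.dkl_ot,
            "dkl_or": result.status.dkl_or,
            "dkl_om_at_k": result.status.dkl_om_at_k,
            "n_residues": result.status.n_residues,
            "params": {
                "chain": config.chain,
                "cutoff": config.cutoff,
                "pad": config.pad,
                "k_grid": list(config.k_grid),
                "scale": str(config.scale) if config.scale else "packaged-default",
                "side_chain_only": config.side_chain_only,
            },
        }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        if config.plot:
            _plot_profiles(out_dir / "profiles.png", result, frag_rows, label)
        root.info("run complete: rd=%.6f k=%.2f n=%d",
                  result.status.rd, result.status.k, result.status.n_residues)
        return RunBundle(out_dir, summary, result, frag_rows)
    finally:
        root.removeHandler(handler)
        handler.close()


def _fmt(x: float) -> str:
    return f"{x:.8g}"


def _write_profiles(path: Path, cloud, result: core.ChainResult) -> None:
    lines = ["res_id\tres_name\tT\tO\tM\tR\tO_minus_T"]
    for i, (rid, name) in enumerate(zip(cloud.res_ids, cloud.res_names)):
        rid_s = f"{rid[0]}{rid[1]}{rid[2]}"
        lines.append("\t".join([
            rid_s, name,
            _fmt(result.t.values[i]), _fmt(result.o.values[i]),
            _fmt(result.m.values[i]), _fmt(result.r.values[i]),
            _fmt(result.o.values[i] - result.t.values[i]),
        ]))
    path.write_text("\n".join(lines) + "\n")


def _write_fragment_table(path: Path, form: str,
                          rows: list[fragments.FragmentStatusRow]) -> None:
    lines = ["\t".join(_FRAGMENT_COLUMNS)]
    for row in rows:
        s = row.status
        lines.append("\t".join([
            form, row.fragment.label, str(row.fragment.start), str(row.fragment.end),
            _fmt(s.rd), _fmt(s.k), _fmt(s.dkl_ot), _fmt(s.dkl_or), str(s.n_residues),
        ]))
    path.write_text("\n".join(lines) + "\n")


def _read_fragment_table(path: Path) -> list[fragments.FragmentStatusRow]:
    lines = path.read_text().rstrip("\n").split("\n")
    if lines[0].split("\t") != _FRAGMENT_COLUMNS:
        raise InputError(f"{path}: not a fragment status table")
    rows = []
    for line in lines[1:]:
        form, label, start, end, rd_v, k_v, d_ot, d_or, n = line.split("\t")
        rows.append(fragments.FragmentStatusRow(
            structure_io.FragmentSpec(label, int(start), int(end)),
            core.FodStatus(float(rd_v), float(k_v), float(d_ot), float(d_or),
                           float("nan"), int(n)),
        ))
    return rows


def _plot_profiles(path: Path, result: core.ChainResult,
                   frag_rows, label: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(result.t))
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(x, result.t.values, color="tab:blue", label="T")
    ax.plot(x, result.o.values, color="tab:red", label="O")
    ax.plot(x, result.m.values, color="0.5", label=f"M (K={result.status.k:g})")
    auth = [rid[1] for rid in result.t.index]
    for i, row in enumerate(frag_rows):
        lo = min((j for j, a in enumerate(auth) if a >= row.fragment.start), default=None)
        hi = max((j for j, a in enumerate(auth) if a <= row.fragment.end), default=None)
        if lo is not None and hi is not None and lo <= hi:
            ax.axvspan(lo, hi, alpha=0.12, color=f"C{i % 10}")
    ax.set_xlabel("residue index")
    ax.set_ylabel("normalized hydrophobicity")
    ax.set_title(label)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_runs(out_bundle_dir: str | Path, in_bundle_dir: str | Path,
                 result_dir: str | Path, k_threshold: float = 0.1) -> dict:
    """Compare two completed run bundles (Out form vs In form) fragment by
    fragment; writes comparison TSV + JSON under ``result_dir``."""
    out_dir, in_dir = Path(out_bundle_dir), Path(in_bundle_dir)
    rows_out = _read_fragment_table(out_dir / "fragment_status.tsv")
    rows_in = _read_fragment_table(in_dir / "fragment_status.tsv")
    rows, totals = fragments.compare_states(rows_out, rows_in, k_threshold=k_threshold)

    result_dir = Path(result_dir)
    result_dir.mkdir(parents=True, exist_ok=True)
    lines = ["label\trd_out\tk_out\trd_in\tk_in\tdelta_rd\tdelta_k\tchanged"]
    payload_rows = []
    for row in rows:
        so, si = row.status_out, row.status_in
        rec = {
            "label": row.label,
            "rd_out": so.rd if so else None,
            "k_out": so.k if so else None,
            "rd_in": si.rd if si else None,
            "k_in": si.k if si else None,
            "delta_rd": row.delta_rd,
            "delta_k": row.delta_k,
            "changed": row.changed,
        }
        payload_rows.append(rec)
        lines.append("\t".join(
            "" if rec[c] is None else (_fmt(rec[c]) if isinstance(rec[c], float) else str(rec[c]))
            for c in ["label", "rd_out", "k_out", "rd_in", "k_in",
                      "delta_rd", "delta_k", "changed"]
        ))
    (result_dir / "comparison.tsv").write_text("\n".join(lines) + "\n")
    payload = {"rows": payload_rows, "totals": totals, "k_threshold": k_threshold}
    (result_dir / "comparison.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return payload
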