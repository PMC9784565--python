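"""Score a real transporter pair from the PDB (needs network or a warm cache).

Downloads the inward- and outward-facing forms of a bacterial ferroportin
homologue (PDB 5AYO / 5AYM), scores chain A of each, and compares their
transmembrane helices using the fragment tables shipped with the package.
"""

import sys
from pathlib import Path

import fodm
from fodm import RunConfig, compare_runs, run_analysis
from fodm.errors import InputError

DATA = Path(fodm.__file__).parent / "data" / "fragments"
CACHE = Path("pdb_cache")

try:
    for form, acc in [("out", "5AYM"), ("in", "5AYO")]:
        bundle = run_analysis(RunConfig(
            pdb=acc, chain="A", cache_dir=CACHE,
            fragments=DATA / f"{acc}.tsv", out_dir=f"run_{acc}", label=form))
        print(f"{acc} ({form}ward-facing): RD = {bundle.summary['rd']:.3f}  "
              f"K = {bundle.summary['k']:.1f}  n = {bundle.summary['n_residues']}")
except InputError as exc:
    sys.exit(f"could not retrieve the structures ({exc}); "
             "run with network access or a populated pdb_cache/")

payload = compare_runs("run_5AYM", "run_5AYO", "cmp_5AY")
changed = [r["label"] for r in payload["rows"] if r["changed"]]
print(f"helices with K shifted by >= 0.1 between forms: {', '.join(changed)}")
print("totals (out/in): sum RD "
      f"{payload['totals']['sum_rd_out']:.2f}/{payload['totals']['sum_rd_in']:.2f}, "
      f"sum K {payload['totals']['sum_k_out']:.1f}/{payload['totals']['sum_k_in']:.1f}")
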