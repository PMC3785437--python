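#!/usr/bin/env python
"""Select the shortest species-diagnostic window from an aligned library.

Demonstrates the sliding-window mini-barcode search on an alignment whose
species are distinguishable only inside a planted 50-column block: the
selector must find a window inside that block, at the shortest width that
still identifies every sequence by its nearest neighbour. Writes per-window
diagnostics at the selected width to results/minibarcode_windows.tsv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from preydiet.minibarcode import select_minibarcode, sliding_window
from preydiet.synthetic import simulate_planted_alignment

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/minibarcode_windows.tsv"))
args = parser.parse_args()

lib, (b0, b1) = simulate_planted_alignment(seed=args.seed)
print(f"alignment: {len(lib)} sequences x {lib.alignment_length} columns; "
      f"diagnostic block at columns {b0}-{b1}")

best = select_minibarcode(lib, w_min=2, w_max=60, required_I=1.0)
if best is None:
    raise SystemExit("no window achieves full identification success")
inside = b0 <= best.start and best.start + best.length - 1 <= b1
print(f"selected mini-barcode: columns {best.start}-{best.start + best.length - 1} "
      f"(width {best.length}), identification success "
      f"{best.identification_success:.3f} over {best.n_evaluated} sequences")
print(f"window lies inside the planted block: {inside}")

args.out.parent.mkdir(parents=True, exist_ok=True)
rows = [dataclasses.asdict(w) for w in sliding_window(lib, best.length)]
pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
print(f"per-window scores at width {best.length} written to {args.out}")
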