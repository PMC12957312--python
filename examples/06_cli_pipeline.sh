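#!/usr/bin/env bash
# End-to-end pipeline via the CLI: simulate a session container, fit
# demixed components, run the geometry and behavioral analyses, and
# aggregate everything into one summary table.
set -euo pipefail

out=$(mktemp -d)
echo "working in $out"

popgeom simulate --seed 1 --out "$out/session.h5"
popgeom demix    --in "$out/session.h5" --tasks A --out "$out/components.csv"
popgeom geometry --in "$out/session.h5" --seed 1 --out "$out/geometry.csv"
popgeom behavior --in "$out/session.h5" --out "$out/behavior.csv"
popgeom report -g "$out/geometry.csv" -b "$out/behavior.csv" \
    --out "$out/summary.csv"

head -25 "$out/summary.csv"
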