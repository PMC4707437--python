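#!/bin/sh
# End-to-end shell pipeline: simulate -> train -> predict -> evaluate.
# Runs in about a minute; all outputs land in ./demo/.
set -e

deepcnf simulate --out-dir demo/data --num-sequences 20 --mean-length 50 --seed 7

deepcnf train --manifest demo/data/manifest.tsv --out demo/model.json \
    --three-state --layers 2 --neurons 8 --window 5 --lam 10 --max-iter 40 --seed 0

deepcnf predict --model demo/model.json --manifest demo/data/manifest.tsv \
    --out-dir demo/pred

cat demo/data/*.labels > demo/observed.labels
deepcnf evaluate --predicted demo/pred/predictions.ss8.fasta \
    --observed demo/observed.labels

deepcnf gradcheck --seed 1
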