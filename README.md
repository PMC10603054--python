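# dynrbp

Prediction and interpretation of dynamic RNA-binding-protein (RBP) binding
events from RNA sequence and in-vivo secondary-structure reactivity.

The package covers the full pipeline:

* **Reactivity scoring** (`dynrbp.icshape`) — per-base structure scores in
  [0, 1] from raw RT-stop / base-density count tables (two DMSO + two NAI
  replicates), with sliding-window winsorized normalization, background
  subtraction and a 200x coverage cutoff (NULL below).
* **Dataset construction** (`dynrbp.dataset`) — top-confidence peaks fixed
  to 101 nt (extended/trimmed around the peak midpoint), negatives sampled
  from the transcriptome, 80/20 train-test and 20% validation splits,
  overlapping k-mer tokenization with `[CLS]`/`[SEP]`, and alignment of
  per-base structure profiles onto tokens.
* **Feature encoders** (`dynrbp.encoder`) — a trainable multi-head
  self-attention encoder producing context-dependent token embeddings
  (full-size preset: 12 layers x 768 units x 12 heads; a small 2-layer,
  64-unit preset for desk-scale training), a static one-hot fallback, and a
  loader for precomputed embedding matrices (HDF5).
* **Binding model** (`dynrbp.model`) — unified alignment of sequence and
  structure features to 128 channels, two multi-scale residual conv stacks
  (kernels 1/3/5/7, depths 1/2/3/4, 32 channels each), channel
  concatenation, and a pyramid of residual conv blocks with stride-2
  max-pooling down to a single position, ending in a sigmoid probability.
  Also single-base variant-effect scoring (p_ref, p_alt, delta).
* **Training** (`dynrbp.training`) — Adam (batch 32, lr 1e-3, weight decay
  1e-6) with linear warm-up, early stopping on validation loss with
  best-checkpoint restore, and ROC-AUC evaluation.
* **Interpretation** (`dynrbp.interpret`) — attention-based motif calling
  (fragments above the sequence mean, at least 10x the floor score, minimum
  6 nt), PWM construction (MEME output), token-to-nucleotide saliency
  spreading, and expected-gradients attribution.
* **Synthetic data** (`dynrbp.synth`) — random transcriptomes,
  confidence-ranked peaks, motif-planted labelled datasets with structure
  preferences, and Poisson count tables from a known reactivity truth.

The neural-network stack runs on a small numpy reverse-mode autodiff engine
(`dynrbp.autograd` / `dynrbp.nn`); no GPU or deep-learning framework is
required.

## CLI

One entry point with subcommands; every run writes a `manifest.json`
(config echo, seed, package version, input checksums) beside its outputs.

```bash
# synthetic fixture (FASTA + BED + counts TSV + samples + truth JSON)
dynrbp simulate --seed 7 --out sim/

# per-base reactivity from a counts table
dynrbp icshape-score --counts sim/counts.tsv --alpha 0.25 \
    --window-size 200 --window-step 5 --out scores/

# 101-nt labelled samples and train/validation/test splits
dynrbp build-data --peaks sim/peaks.bed --fasta sim/transcriptome.fasta \
    --n-pos 5000 --n-neg 10000 --seed 7 --out data/

# train / predict / interpret / variant effect
dynrbp train --data data/ --seed 7 --out run/
dynrbp predict --model run/model.npz --data data/test.tsv --out preds.tsv
dynrbp interpret --model run/model.npz --data data/test.tsv \
    --mode motifs --out motifs/
dynrbp variant-effect --model run/model.npz --data data/test.tsv \
    --position 40 --alt G --out effect.json
```

Cross-condition ("dynamic") prediction is plain
`dynrbp predict --model <trained-on-A> --data <condition-B>`.

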