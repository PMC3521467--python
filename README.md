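# nucloc

Prediction of nuclear vs. non-nuclear protein localization from sequence
profiles, with mining of gapped-dipeptide signatures that behave like
nuclear localization / export signals.

The pipeline treats a protein as a document of gapped-dipeptide "words":

1. **Profile** — an `n x 20` PSSM per protein, read from PSI-BLAST ASCII
   output or synthesized from BLOSUM62 rows so everything runs offline.
2. **Smooth** — each profile row is summed with its `w` surrounding rows
   (default `w=7`, zero-padding at the termini) and mapped into (0, 1) with
   a logistic function.
3. **Words** — every gapped-dipeptide `AdB` (amino acid A, gap `d`, amino
   acid B; `d <= 13` by default, 5 600 words) is weighted by the sum of
   products of the normalized smoothed entries at its anchored positions,
   then the vector is max-scaled into [0, 1].
4. **Reduce** — a from-scratch probabilistic latent semantic indexing
   (PLSI) aspect model (`P(w,d) = P(d) Σ_t P(w|t) P(t|d)`, EM-fitted,
   default 80 topics) reduces words to topic weights; held-out proteins are
   folded in with `P(w|t)` frozen. Alternatively, class-preferred topics
   yield gapped-dipeptide *signatures* (default 10 topics x up to 20 words
   per class) and only those word weights are used.
5. **Classify** — an RBF-kernel SVM with grid-tuned `(c, gamma)`, seeded
   stratified cross-validation, and probability outputs.

Evaluation reports sensitivity, specificity, accuracy and MCC from pooled
five-fold confusion counts. A synthetic generator plants basic (K/R/H-rich)
or hydrophobic (L/I/V/F/M) motifs so every stage is testable without any
database download. A curated signature list (183 nuclear + 183 non-nuclear
words) ships with the package.

## CLI

```sh
# synthetic labelled dataset (FASTA + labels TSV + profile directory)
nucloc generate --out data/ --n-nuclear 100 --n-non-nuclear 100 --seed 1

# sparse gapped-dipeptide feature vectors
nucloc features --fasta data/sequences.fasta --profiles data/profiles --out features.tsv

# fit profile->words->PLSI->SVM and persist the bundle
nucloc train --fasta data/sequences.fasta --profiles data/profiles \
             --labels data/labels.tsv --out model.pkl --mode plsi --seed 1

# mine signatures (signature-mode pipeline)
nucloc signatures --fasta data/sequences.fasta --profiles data/profiles \
                  --labels data/labels.tsv --out signatures.tsv --seed 1

# predict new proteins
nucloc predict --model model.pkl --fasta new.fasta --out predictions.tsv

# cross-validated evaluation (pooled confusion counts + metrics)
nucloc evaluate --fasta data/sequences.fasta --profiles data/profiles \
                --labels data/labels.tsv --out report.tsv --seed 1
```

Key flags: `--window`, `--max-gap`, `--topics`, `--folds`,
`--topics-per-class`, `--words-per-topic`, `--mode {plsi,signatures}`,
`--seed`, `--strict-profiles` (fail instead of falling back to
pseudo-profiles). Missing profiles fall back to BLOSUM62 pseudo-profiles
by default.

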