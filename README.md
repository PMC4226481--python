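# erpspell

An offline P300 matrix-speller study *in silico*: stimulus scheduling
for three speller paradigms, a synthetic ERP-EEG generator, the
standard shrinkage-LDA decoding pipeline, and the evaluation statistics
that compare the paradigms.

**Who it is for.** BCI researchers and methods developers who want a
fully testable, end-to-end P300-speller pipeline whose every stage —
oddball scheduling, epoching, feature selection, regularized
classification, letter decoding, ITR accounting, within-subject
statistics — can be verified against known ground truth, because the
"subjects" are simulated with known ERP structure.

## The paradigms

A 6×6 matrix holds 36 symbols (A–Z, 1–9, `_`). Spelling one letter is a
2 s countdown plus 10 *sequences*; a sequence is 12 flashes (135 ms
flash + 50 ms gap) in which every symbol lights up exactly twice.

- **RC** — classic row–column speller: the 6 physical rows and 6
  physical columns flash in random order.
- **RASP** — random set presentation: each sequence uses a freshly
  shuffled *virtual* 6×6 matrix, so on-screen neighbours of the target
  rarely co-flash with it (fewer adjacency errors).
- **RASP-F** — RASP with semi-transparent face overlays: virtual rows
  carry the user's own face, virtual columns other faces (50:50).
  Face stimuli add N170 and face-familiarity N400f components on top of
  the P300, making target flashes more discriminable.

## The decoding model

Epochs (−200…800 ms, 100 Hz, 29 channels, baseline-corrected) are
summarised by mean amplitudes over 8 discriminative intervals chosen on
training data from the signed-r² map

$$\operatorname{sgn} r^2(c,t) = \operatorname{sign}(\mu_1-\mu_2)\,
\left[\tfrac{\sqrt{N_1 N_2}}{N_1+N_2}\,\tfrac{\mu_1-\mu_2}{\sigma}\right]^2,$$

giving a 29 × 8 = 232-dimensional feature vector per flash. A
regularized LDA scores each flash, with the covariance shrunk
analytically toward a scaled identity (Schäfer–Strimmer):
Σ̂ = (1−γ)S + γνI, w = Σ̂⁻¹(μ₁−μ₂). Letter decoding accumulates flash
scores over all sets containing each symbol and takes the argmax.
Performance is reported as accuracy P(n) versus number of sequences n
and as the Wolpaw information transfer rate

$$B = \log_2 N + P\log_2 P + (1-P)\log_2\tfrac{1-P}{N-1}
\quad\text{[bits/selection]},$$

converted to bits/min with the selection duration
(countdown + n·12·0.185 s).

## Worked example

```bash
python examples/03_decode_one_subject.py
```

simulates one subject (three conditions, training sentence
`BRAIN_COMPUTER_INTERFACE`, test sentence `KOREAUNIVERSITY`) and prints,
per condition, the shrinkage intensity, the 8-fold chronological
cross-validated per-flash accuracy, and the accuracy / ITR curves:

```
RASP_F  (shrinkage gamma = 0.0204, per-flash CV accuracy = 0.922)
  sequences :     1      2      3  ...
  accuracy  :  0.87   1.00   1.00  ...
  bits/min  :  55.7   48.2   35.8  ...
  1-sequence decode: KOREFZNIVERSITY (truth KOREAUNIVERSITY)
```

Reading: with a single sequence the face-familiarity speller already
decodes 13/15 letters (87 %); at 55.7 bits/min it far outpaces the RC
condition (here 0.47 accuracy, 20.4 bits/min) because the N170/N400f
deflections add class information to every target flash. ITR *drops*
with more sequences even as accuracy rises, since each extra sequence
costs 2.22 s per letter.

Other examples: `01_build_schedule.py` (schedule structure and
target-to-target intervals), `02_simulate_and_average.py` (component
amplitudes recovered from epochs), `04_cohort_statistics.py`
(repeated-measures ANOVA, self- vs non-self-face sign test, TTI
profile). A thin CLI mirrors the file workflow:
`erpspell schedule | generate | preprocess | run`.

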