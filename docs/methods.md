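# Methods

## Problem

The package models an optical-biopsy workflow for cardiac tissue: a probe
with one illumination fiber and five collection fibers (R1–R5 at 210, 345,
480, 615, 750 µm center-to-center separation) records reflectance spectra
(500–1100 nm) from 1.6 mm layered constructs of myocardium and aortic
tissue, the aorta standing in for fibrosis. A 1-D CNN classifies each
spectrum (or a two-fiber concatenation) into the construct arrangement it
came from. Three classification problems probe depth of a fibrotic inset,
fibrotic volume fraction, and permuted 50/50 arrangements; a binary
myocardium-vs-aorta problem validates the network.

## Construct labels and study designs

A construct is eight 200 µm sections encoded as an 8-character binary
string, top layer leftmost ("0" myocardium, "1" aorta). The four designs:

| design   | classes | proximal threshold |
|----------|---------|--------------------|
| binary   | 00000000, 11111111 | – |
| depth    | 11000000, 00110000, 00001100, 00000011, + both pure | 4 |
| volume   | 0–8 aortic sections, filled top-down starting at layer 2 | 1 |
| permuted | six 50/50 arrangements (configurable) | min pairwise distance (4 for the defaults) |

The depth design is the set of four non-overlapping positions of a
two-section (400 µm) inset plus the two pure constructs: this is the only
composition consistent with a six-class depth study in which a distance-4
pair is the minimal difference between inset positions. Its proximal
threshold is fixed at 4 (the inset-to-inset minimum) rather than the global
minimum pairwise distance of the class set, which would be 2 via the pure
constructs; the worked proximal example (prediction 11000000 for truth
00110000) anchors this choice. The volume design reads "replace the
top-most layers first, starting with the second layer" as: first step
01000000, then top-down fill (11000000, 11100000, …). The exact six
permuted arrangements are not recoverable from the source figures, so the
default set spans block and alternating heterogeneity
(11110000/00001111/11001100/00110011/10101010/01010101) and is
user-configurable; the proximal threshold is then derived from the set.

## Accuracy statistic

accuracy = (n_correct + 0.5 · n_similar) / n_total, where n_similar counts
proximal predictions: mispredictions whose Hamming (layer-count) distance
from the truth equals the design's proximal threshold. Hamming distance
operationalizes "tissue composition difference" — each layer is a fixed
12.5 % of the volume, so layer count and composition difference coincide.
Confusion matrices count raw argmax predictions; proximal credit enters
only the scalar. Replicate accuracies are reported as mean ± sample (n−1)
stddev over the replicates that survive an exclusion rule: replicates below
chance level 1/K are dropped, with each exclusion logged (the protocol's
"very low accuracy" exclusion is otherwise unspecified; chance level is the
natural scale and is configurable).

## Forward simulator

The generator produces the statistical structure the pipeline assumes,
without photon-transport simulation (a deliberate trade: Monte Carlo
transport is orders of magnitude more expensive and none of the pipeline's
logic depends on radiative-transfer realism).

* **Base spectra.** Smooth positive functions on the grid; aorta brighter
  than myocardium at every wavelength with a wavelength-dependent ratio, so
  the two tissues remain distinguishable after mean normalization. The lamp
  is a broad tungsten-halogen-like envelope. Exact shapes are free
  parameters of `TissueOpticalModel`.
* **Depth weighting.** A fiber at separation r_sd samples a banana-shaped
  path with modal depth z_max = r_sd/(2√2) (74 µm for R1, 265 µm for R5).
  Layer k (depth (k+0.5)·200 µm) receives weight ∝
  exp(−|depth_k − z_max|/δ), normalized to sum 1. The decay scale δ = 350 µm
  reflects the deep sensitivity implied by millimetre-scale transport mean
  free paths in cardiac tissue while keeping superficial layers dominant;
  the exponential form is a one-parameter stand-in for the banana profile,
  of which only the modal depth is specified.
* **Amplitude and noise.** Collected amplitude scales as (210/r_sd)², and
  linearly with exposure time (reference 30 ms). Noise is additive Gaussian
  read noise (σ = 0.005 in clean-signal units) plus shot noise
  (0.035·√signal), clipped at zero; both σ are defined *per native
  spectrometer pixel* (3587 pixels). These defaults put the per-pixel
  tissue SNR at R5 and 30 ms near 5 — the instrument's working point — with
  SNR decreasing in fiber distance and increasing in exposure. On a reduced
  grid each sample stands for a bin of native pixels and the noise shrinks
  by √(bin factor), exactly as under physical pixel binning: downsampling
  the grid changes resolution, not the information content of a spectrum.
  Without this convention a coarse grid would silently starve the
  low-amplitude distal fibers of the wavelength-averaging the real
  instrument provides and invert the fiber hierarchy.
* **Subject variability.** Each rebuild of each class carries a log-normal
  gain (σ = 0.15; removed by normalization, kept for raw-intensity realism)
  and a smooth multiplicative spectral tilt (exp of a random low-order
  Legendre polynomial, amplitude 0.02). The tilt survives normalization and
  is shared by all spectra of that rebuild, which is precisely what makes
  subject-wise hold-out harder than a random split. A smaller per-spectrum
  tilt (amplitude 0.008) emulates probe repositioning between measurements.
* **Protocol.** Each study emits 10 spectra per class × rebuild × fiber at
  30 ms, 3 rebuilds per class by default: 1350 spectra for the volume study
  and 900 for the permuted study. The calibration standard is 0.99 × lamp
  with the same noise model.

What the generator does **not** emulate: absorption chromophores
(hemoglobin bands), polarization, anisotropy, instrument drift, or any
angular structure of real banana paths. Passing tests therefore demonstrate
that the pipeline recovers the class structure this model encodes — depth-
and composition-dependent spectral mixtures under realistic noise and
subject variability — not that the measured-data accuracies would be
reproduced.

## CNN and training protocol

Three Conv(8/10/12 filters, kernel 5, stride 1, no padding) → ReLU →
MaxPool(2, non-overlapping) blocks, flatten, one affine projection to the
class scores, softmax (sigmoid for binary). The affine projection is the
minimal completion of a topology whose final listed layer is the
softmax/sigmoid itself; a pooling "stride 0" is read as non-overlapping
pooling (stride = pool size), the only executable interpretation. Input
spectra are divided by their mean during feature building and the per-sample
mean is subtracted at the first layer.

Training: full-batch ADAM (lr 1e-4, β = 0.9/0.999), cross-entropy loss,
stop when the training loss has not decreased for 400 epochs or at 1000
epochs — the early-stop metric is the *training* loss, as specified; the
stratified 30 % validation split is retained for monitoring only, and final
weights are kept (no best-weight restoration). Ten replicates per
assessment, each from a derived seed; each replicate draws its own
subject-wise split, so the held-out rebuild rotates across replicates and
replicate scatter includes subject-level variability. Argmax ties resolve
to the lowest class index. The implementation is NumPy (einsum over sliding
windows); with full-batch gradients it is exactly deterministic given the
seed.

## Numerical and desk-scale choices

* Default grid: 3587 uniform samples on [500, 1100] nm (spacing ≈0.167 nm;
  a 20-sample Gaussian kernel is ≈3.3 nm). Tests and the analysis drivers
  run on reduced grids of 65–257 samples and, where noted, a reduced epoch
  budget; architecture, optimizer, protocol, and noise model are unchanged.
  The problem sizes used by each test are stated in the test module.
* SNR is the band-averaged per-wavelength mean/stddev across replicates
  (sample stddev); identical replicates return an infinite-SNR sentinel.
  Whether the instrument's SNR was defined per-wavelength or on integrated
  intensity is not recoverable; the per-wavelength form is standard practice
  and scale-invariant.
* Calibration divides a mean-normalized spectrum by the mean-normalized
  white-standard spectrum and re-normalizes, preserving mean-1 inputs to
  the CNN. The pipeline default is *uncalibrated* normalized spectra
  (calibration demonstrably changes little and couples the classifier to
  one spectrometer); a config flag turns it on.
* Difference-to-reference curves are computed against the *mean* pure-aorta
  spectrum (deterministic, as opposed to random per-spectrum pairing) and
  smoothed with `scipy.ndimage.gaussian_filter1d` (reflect boundary).
* Degenerate inputs error loudly: zero-mean spectra, zero-variance
  correlations, single-rebuild classes, class sets with duplicate labels.

## Known limitations

The forward model's 1-D mixture family makes deep-layer information weaker
than shallow-layer information for every fiber; deep inset positions are
separated mainly through the distal fibers and partially through proximal
credit, mirroring the qualitative structure but not the absolute accuracy
of measured data. Measured-data accuracies additionally depend on
instrument specifics (etaloning, fiber coupling, bending) that the
generator does not model. The optional loader for the deposited measured
dataset is a stub extension point (`read_dataset` covers any data arranged
in the package's CSV layout); the repository's native layout is
undocumented.
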