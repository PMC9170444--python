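# fuzzyseg

Fuzzy C-means segmentation of brain MR images, with an improved variant
that combines **intuitionistic fuzzification**, a **Gaussian kernel-induced
distance** and a **spatial neighbourhood constraint** — plus the evaluation
stack around it: cluster-validity indices, a spin-echo phantom simulator
with ground truth, volumetry/confusion metrics, and ROC-based tumor-grading
statistics for per-subject imaging parameters (MK/AK/RK, Cho/Cr, Cho/NAA).

It is written for researchers in quantitative neuroimaging who want a
reproducible, NIfTI-native reference implementation of spatially
constrained kernel FCM for tissue/tumor segmentation, and a synthetic test
bed when no annotated patient data are available.

## The model

Classical FCM partitions the in-brain voxel intensities
$M=\{m_1,\dots,m_n\}$ into $f$ fuzzy clusters by minimising

$$E_l(B,A)=\sum_{x=1}^{f}\sum_{y=1}^{n} b_{xy}^{\,l}\,\lVert m_y-a_x\rVert^2 ,
\qquad \sum_x b_{xy}=1,$$

with the familiar alternating updates
$a_x=\sum_y b_{xy}^l m_y / \sum_y b_{xy}^l$ and
$b_{xy}\propto \lVert m_y-a_x\rVert^{-2/(l-1)}$.

The improved algorithm first maps the min–max-normalised gray level
$b_0$ of each voxel to an intuitionistic fuzzy triplet

$$b=b_0^2,\quad a=(1-b_0)^2,\quad \pi=2b_0(1-b_0),\qquad b+a+\pi=1,$$

and clusters the membership image with a Gaussian kernel distance
$\lVert\varphi(u)-\varphi(v)\rVert^2 = 2\bigl(1-e^{-(u-v)^2/\delta^2}\bigr)$
regularised by each voxel's neighbourhood mean $\bar m_y$:

$$a_x=\frac{\sum_y b_{xy}^l\,(m_y+\theta\bar m_y)}{(1+\theta)\sum_y b_{xy}^l},
\qquad
b_{xy}\propto\Bigl[\,d_\varphi(m_y,a_x)+\theta\, d_\varphi(\bar m_y,a_x)\Bigr]^{-1/(l-1)} .$$

After each sweep the hesitation degree $\pi_y$ sharpens the memberships:
non-winning entries are scaled by $\pi_y$ and the winner absorbs the
released mass, preserving the argmax and the unit column sums. Iteration
stops when the largest membership change drops below a tolerance, and the
crisp segmentation is the voxel-wise maximum membership.

Partition quality is compared with the partition coefficient
$V_{pc}=\tfrac1n\sum b_{xy}^2$, the partition entropy
$V_{pe}=-\tfrac1n\sum b_{xy}\ln b_{xy}$ and the Xie–Beni index
$V_{xb}=\sum b_{xy}^l r_{xy}^2 / (n\min_{x\neq e}|a_x-a_e|^2)$.

The phantom simulator paints concentric ellipsoidal tissue shells
(CSF/GM/WM and an off-center tumor blob) with spin-echo intensities
$S=\beta(1-e^{-TR/T_1})e^{-TE/T_2}$ at TR = 1980 ms, TE = 2.28 ms and
1 mm³ voxels, and adds seeded Gaussian, Rician or salt-and-pepper noise.

## Worked example

```python
import fuzzyseg as fs

# a noisy 64x64x64 four-tissue phantom (sigma = half the smallest
# class contrast, about 4% of the white-matter signal)
sigma = 0.5 * fs.min_class_contrast(fs.default_tissues())
ph = fs.make_phantom((64, 64, 64), noise_model="gaussian",
                     noise_level=sigma, seed=11)

res = fs.IntuitionisticKernelFCM(ph.image, n_clusters=4).fit(seed=0)
print(res.summary())

matched = fs.match_labels(res.label_map(), ph.labels, ph.image.mask)
print(fs.overall_accuracy(matched, ph.labels, ph.image.mask))
```

prints

```
IntuitionisticKernelFCM segmentation results
==============================================
voxels (in mask):   100024
clusters:           4
fuzzifier l:        2
iterations:         51
centers (gray):     0.4307, 0.7267, 0.7817, 0.883
Vpc (crispness):    0.8631
Vpe (entropy):      0.3013
Vxb (Xie-Beni):     0.290953
0.8745
```

The four centers recover the CSF/tumor/GM/WM spin-echo signals (0.390,
0.699, 0.766, 0.883); Vpc near 1 and Vpe near 0 indicate a crisp
partition, and 87 % of brain voxels match the ground-truth labels at this
noise level (classical FCM reaches 73 % on the same image — compare with
`fs.FuzzyCMeans(ph.image, 4).fit(seed=0)`).

The same pipeline is scriptable from the shell:

```bash
fuzzyseg phantom --shape 64,64,64 --noise-level 0.03 --seed 7 \
    --out-image ph.nii --out-labels truth.nii
fuzzyseg segment --input ph.nii --algorithm ikfcm --clusters 4 --seed 0 \
    --out-labels seg.nii --out-report report.json
fuzzyseg evaluate --pred seg.nii --truth truth.nii --out eval.json
fuzzyseg roc --table parameters.csv --out grading.csv
```

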