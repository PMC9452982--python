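# petfuse

Mutual-information rigid registration and fusion of PET/CT slice pairs,
with cellular-neural-network edge extraction of the CT reference, for
localizing high-metabolism (high FDG-uptake) regions — e.g. lymphoma
lesions monitored under PD-1 checkpoint-inhibitor therapy — against
anatomy. A synthetic phantom generator with known ground truth validates
the pipeline end to end, and a small utility tallies RECIST response
categories (CR/PR/SD/PD) into the percentages a clinical efficacy table
reports.

## The method

Two images of the same anatomy — a floating PET image *U* and a fixed
reference *D* — are treated as random variables over their gray levels.
From the joint histogram of co-located gray-level pairs, with
j<sub>UD</sub>(u,d) = n<sub>ud</sub>/N and marginals j<sub>U</sub>,
j<sub>D</sub>, the mutual information (in bits)

> I(U, D) = Σ<sub>u,d</sub> j<sub>UD</sub>(u,d) log₂ [ j<sub>UD</sub>(u,d) / (j<sub>U</sub>(u) · j<sub>D</sub>(d)) ]
>         = H(U) + H(D) − H(U, D)

peaks when the images are correctly aligned. Registration finds

> u\* = argmax<sub>T</sub> I(U ∘ T, D)

over rigid transforms T = (β, t<sub>x</sub>, t<sub>y</sub>) — rotation β
about the image center plus translation — with a deterministic coarse
grid search followed by coordinate-descent refinement. PET edges are too
blurred to extract, so by default *D* is not the raw CT but its **edge
image**, computed by a Chua–Yang cellular neural network: a lattice of
locally coupled analog cells evolving by
dx/dt = −x + A∗y + B∗u + z with output y = 0.5(|x+1| − |x−1|), run with
the classical edge-detection template until the steady-state output
marks intensity transitions. MI is always estimated over the transform
overlap region only, and the warped PET is resampled by backward warping
with bilinear interpolation.

After registration the PET is overlaid on the CT through a hot colormap,
and high-uptake regions are segmented by thresholding at a fraction of
the PET maximum; masks are scored against ground truth with pixel
accuracy, Dice and Jaccard.

## Worked example

```python
import petfuse as pf

ph = pf.generate_phantom(seed=1, size=128)     # CT + misaligned PET
print(ph.true_transform)
# RigidTransform(beta=0.004728649880102687, tx=7.207419141214965, ty=-5.69344619648586)

res = pf.register(ph.pet, ph.ct)               # MI vs the CT edge image
print(res.u_star, f"{res.final_mi:.4f} bits in {res.n_evals} evaluations")
# RigidTransform(beta=-0.01874999999999999, tx=-7.0, ty=6.0) 0.1252 bits in 1615 evaluations
```

The recovered transform approximates the *inverse* of the applied
misalignment (≈ (−0.005, −7.18, +5.73)): applying it to the PET puts the
lesion back into the CT frame. Segmenting the realigned PET at 40% of
its maximum and comparing with the generator's lesion mask:

```python
realigned, _ = pf.resample(ph.pet, res.u_star)
seg = pf.segment_high_uptake(realigned, "fraction_of_max", 0.4)
print(pf.accuracy_metrics(seg.mask, ph.lesion_mask))
# {'pixel_accuracy': 0.9954, 'dice': 0.9097, 'jaccard': 0.8344}
```

The same pipeline is available from the shell:

```sh
petfuse phantom --seed 1 --outdir ph
petfuse register --pet ph/pet.nii --ct ph/ct.nii --out-transform t.txt --trace trace.csv
petfuse fuse --pet ph/pet.nii --ct ph/ct.nii --alpha 0.5 --output fused.png
petfuse segment --pet ph/pet.nii --output mask.png
petfuse report responses.csv
```

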