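# avpconn

Connectomic analysis of the *Drosophila* anterior visual pathway (AVP): from
raw synapse tables to neuron subtype classification, dendritic-arbor
morphometrics, and predicted visual receptive fields of ring (ER) neurons.

The AVP carries visual information used for navigation through four
neuropils in sequence — medulla → anterior optic tubercle (AOTUsu) → bulb →
ellipsoid body — via three neuron classes: MeTu (medulla-to-tubercle), TuBu
(tubercle-to-bulb) and ER (ring) neurons, which feed the fly's compass
(EPG) neurons.  Given an EM-reconstruction synapse table (pre id, post id,
3-D position, cleft score) and neuron annotations, this package answers:

* which MeTu subtypes exist, from their connectivity fingerprints;
* how the retinotopic medulla map is transformed along the pathway;
* which part of the visual field each ER neuron is predicted to see.

It is written for connectomics researchers working with FlyWire/FAFB-style
synapse exports, and ships a synthetic-connectome generator with planted
ground truth so that every stage can be validated without any download.

## The core quantities

**Regional synaptic weight.**  Within a neuropil region, the weight of a
connection is the synapse count from presynaptic neuron *i* onto
postsynaptic neuron *j*, divided by *j*'s total synapse count in the
region:

    w(i -> j) = N_region(i -> j) / N_region(j)

Contacts only count after filtering (cleft score ≥ 50, no autapses, no
background contacts); postsynaptic neurons with fewer than five regional
connections are dropped.  Type-level weights aggregate all neurons of each
type before normalizing.

**Receptive-field back-tracing.**  The predicted visual field of an ER
neuron assigns each medulla column *c* a direct-pathway value

    D(c) = Σ_b Σ_m  w(b → ER) · w(m → b) · occ(m, c)

over TuBu neurons *b* and MeTu neurons *m*, where the occupancy
occ(*m*, *c*) is the fraction of *m*'s medulla synaptic sites nearest
column *c*.  The indirect (putatively inhibitory) pathway interposes the
bilateral TuTu neurons: I(c) = Σ w(b→ER)·w(t→b)·w(m→t)·occ(m, c).  Because
occupancies sum to one per neuron, Σ_c D(c) = Σ_b w(b→ER)·Σ_m w(m→b) — a
conservation identity the tests enforce.

**Morphometrics.**  Dendritic spans are summarized by a maximum-likelihood
2-D Gaussian (1-sigma ellipse: centroid, semi-axes, angle from the
dorsal–ventral axis); arbor orientations are tested for uniformity with the
axial Rayleigh test (angles doubled, z = nR̄², p = e^{-z}(1 + (2z − z²)/4n)).
Columns map to ommatidial viewing directions by aligning hexagonal lattices
on their equator rows, minimizing unmatched points.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from sklearn.metrics import adjusted_rand_score
from avpconn.config import SynthConfig, PipelineConfig
from avpconn.synth import generate_connectome
from avpconn.pipeline import analyze

synapses, annotations, hulls, truth = generate_connectome(SynthConfig(seed=1))
print(f"contacts: {len(synapses)}, neurons: {len(annotations)}")

result = analyze(synapses, annotations, hulls, PipelineConfig())
labels = [truth.subtypes[m] for m in result.features.index]
print(f"clusters found: {result.labels.nunique()}, ARI vs planted subtypes: "
      f"{adjusted_rand_score(labels, result.labels):.3f}")
print(f"retinotopy (medulla AP vs AOTU DV), Spearman rho: {result.retinotopy_rho:.3f}")

er = "ER4d_R_00"
fld, ell = result.fields[er], result.field_ellipses[er]
print(f"{er}: {fld.covered_columns} covered columns, "
      f"field ellipse ratio {ell.ratio:.2f} at {ell.angle_deg:.1f} deg from vertical")
```

prints

```
contacts: 128635, neurons: 1465
clusters found: 10, ARI vs planted subtypes: 1.000
retinotopy (medulla AP vs AOTU DV), Spearman rho: 0.998
ER4d_R_00: 65 covered columns, field ellipse ratio 3.61 at 4.7 deg from vertical
```

The generator plants ten MeTu-like subtypes (fifty neurons each) with
distinct input-type fingerprints; connectivity clustering recovers them
perfectly (ARI 1.0).  The planted monotone map from anterior–posterior
medulla position to dorsal–ventral tubercle position is recovered with
Spearman ρ ≈ 1.  The ER neuron fed by the vertically-elongated,
azimuth-only retinotopic channel is predicted to see a vertical stripe of
the visual field (ellipse ratio 3.6, near-vertical), whereas ER neurons fed
by the 2-D tiling channel see compact patches (ratio < 2) — the structural
contrast between azimuth-coding and two-dimensional visual channels.

A command-line interface mirrors the library
(`avpconn simulate | filter | weights | traverse | density`).

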