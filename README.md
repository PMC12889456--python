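# tcloop

Conductance-based simulation of rodent and primate thalamocortical loops,
with the analysis suite used to quantify their activity: band-PCA synchrony
angles, mean propagation time (MPT), sleep-spindle metrics and sigma-band
spectral density.

## The scientific problem

Thalamocortical circuits generate sleep spindles (brief 10–16 Hz
oscillations) and control how synchronously cortical populations fire.
Two parallel sub-circuits coexist: the *core* (focal thalamocortical
projections, driving) and the *matrix* (diffuse projections an order of
magnitude wider, modulatory), with opposite receptor arrangements —
metabotropic (mGluR) corticothalamic / ionotropic (AMPA) thalamocortical
synapses in the core, and the reverse (NMDA down, mGluR up) in the matrix.
The reticular nucleus (TRN) can inhibit the same relay (TC) cells that
excite it (*closed* loop), different ones (*open* loop), or a mixture
(*hybrid*).  Rodents lack the thalamic interneurons (IN) that make up a
third of primate thalamic neurons.  `tcloop` implements these circuits as
Hodgkin–Huxley-type single-compartment neurons — TRN and TC cells carry a
low-threshold Ca²⁺ current I_T (activation exponent 2 and 3 respectively)
whose rebound bursts pace the loop, and TC cells add the
hyperpolarization-activated I_H with slow/fast open and locked states —
connected by kinetic synapse models (first-order ionotropic binding;
a GABA_B/mGluR second-messenger cascade with Hill saturation
s^n/(s^n+K_d)).  A 3-D parameter cube scales core strength, matrix
strength and cortico-cortical mixing around a balanced control case.

The membrane equation, with currents outward-positive:

    Cm dV/dt = −g_leak(V−E_leak) − I_Na − I_K − I_T − I_H − I_syn + I_ext

Analysis metrics: for each activity band (a contiguous volley of
population spiking), PCA of the z-scored (time, neuron) events gives the
orientation θ of the first principal component — θ = 90° means a vertical,
synchronous band, and deviation = |90° − θ| measures temporal tilt.
Mirror-symmetric "boomerang" bands force full-band PCA artificially
vertical; PCA on the upper half of the band recovers the true arm tilt.
MPT is the band's time extent along PC1 divided by the number of active
neurons (ms/neuron; 0 = perfectly synchronous).  Sleep spindles are
detected on 9–13 Hz bandpassed averages of 5-neuron (core, matrix) or
10-neuron (mixed) cortical groups: envelope peaks ≥ 30 % of the largest
peak, ≥ 0.5 s apart, with durations between flanking envelope minima.

## Worked example

```python
from tcloop import build_network, simulate
from tcloop.synchrony_analysis import analyze_raster

net = build_network("rodent", "closed")        # control-case weights
res = simulate(net, duration=3000.0)           # 500 ms settling + pulse at 500 ms
bands = [m for m in analyze_raster(res.rasters["Ctx_core"],
                                   half_band=True, exclude_before_ms=500.0)
         if m.analyzable]
worst = max(bands, key=lambda m: m.deviation_deg)
print(f"{len(bands)} core cortical bands")
print(f"most tilted: deviation {worst.deviation_deg:.2f} deg, "
      f"MPT {worst.mpt_ms_per_neuron:.2f} ms/neuron")
```

prints (exact numbers are deterministic for a given version):

```
23 core cortical bands
most tilted: deviation 35.87 deg, MPT 42.88 ms/neuron
```

i.e. the closed rodent loop breaks into ~10 Hz cycle volleys; full-band
PCA sees them as near-vertical (the boomerang symmetry artifact), while
the half-band correction reveals arm tilts of tens of degrees.  A CLI
wraps the same pipeline (`tcloop simulate`, `tcloop bands`,
`tcloop spindles`).

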