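# Pupil-control network.
#
# Nuclei (circles): leaky-integrator units, one per anatomical cell group.
# Functional components (rectangles): visual cortex, cerebellum, amygdala.
# The iris plant is an actuator translating antagonist drives into pupil
# diameter; its constants are scaling-class parameters (unit choices).
#
# The edge set is a provisional reconstruction from the anatomy of pupil
# control; revising it requires editing only this file.
groups:
  eye:
    components:
      R:
        external: [light, us_light]
        params:
          epsilon: {value: 0.1, class: empirical}
  thalamus:
    components:
      LGN: {}
      PULV: {}
  brainstem:
    components:
      PTA: {}
      EWpg: {}
      SC: {}
      LC: {}
  hypothalamus:
    components:
      LH: {}
      DMH: {}
      SCN: {}
      PVN: {}
      VLPO: {}
  autonomic:
    components:
      IML: {}
      SCG: {}
      CG: {}
  cortex:
    components:
      Cortex:
        kind: functional
        impl: cortex
        output_shape: vector(16)
        external: [identity]
        ports:
          surprise: {direction: out, shape: scalar}
  cerebellum:
    components:
      CB:
        kind: functional
        impl: cerebellum
        external: [us_light]
  amygdala:
    components:
      AMY:
        kind: functional
        impl: amygdala
        external: [identity, valence, arousal]
        ports:
          surprise: {direction: in, shape: scalar}
components:
  plant:
    kind: actuator
    impl: pupil_plant
    ports:
      sphincter: {direction: in, shape: scalar}
      dilator: {direction: in, shape: scalar}
    params:
      d_rest: {value: 4.0, class: scaling}
      d_min: {value: 2.0, class: scaling}
      d_max: {value: 8.0, class: scaling}
      g_s: {value: 3.0, class: scaling}
      g_d: {value: 3.0, class: scaling}
connections:
  # parasympathetic (constriction) chain: 4 hops from retina to sphincter
  - {source: eye.R, target: brainstem.PTA, kind: excitatory}
  - {source: brainstem.PTA, target: brainstem.EWpg, kind: excitatory, receptor: nAChR}
  - {source: brainstem.EWpg, target: autonomic.CG, kind: excitatory}
  - {source: autonomic.CG, target: plant.sphincter, kind: excitatory, receptor: mAChR}
  # sympathetic (dilation) chain: 5 hops from amygdala to dilator
  - {source: amygdala.AMY, target: hypothalamus.LH, kind: excitatory}
  - {source: hypothalamus.LH, target: hypothalamus.DMH, kind: excitatory}
  - {source: hypothalamus.DMH, target: hypothalamus.PVN, kind: excitatory}
  - {source: hypothalamus.DMH, target: autonomic.IML, kind: excitatory}
  - {source: hypothalamus.PVN, target: autonomic.IML, kind: excitatory}
  - {source: autonomic.IML, target: autonomic.SCG, kind: excitatory, receptor: nAChR}
  - {source: autonomic.SCG, target: plant.dilator, kind: excitatory, receptor: a1}
  # circadian / arousal-regulating branch
  - {source: eye.R, target: hypothalamus.SCN, kind: excitatory}
  - {source: hypothalamus.SCN, target: hypothalamus.VLPO, kind: excitatory}
  - {source: hypothalamus.VLPO, target: brainstem.LC, kind: inhibitory, receptor: GABA}
  - {source: amygdala.AMY, target: brainstem.LC, kind: excitatory}
  # noradrenergic shunt of the light reflex (fear-inhibited light reflex)
  - {source: brainstem.LC, target: brainstem.EWpg, kind: shunting, receptor: a2}
  # visual recognition routes
  - {source: eye.R, target: thalamus.LGN, kind: excitatory}
  - {source: thalamus.LGN, target: cortex.Cortex, kind: excitatory}
  - {source: eye.R, target: brainstem.SC, kind: excitatory}
  - {source: brainstem.SC, target: thalamus.PULV, kind: excitatory}
  - {source: thalamus.PULV, target: amygdala.AMY, kind: excitatory, plastic: true}
  # learning pathways (the only plastic connections)
  - {source: cortex.Cortex, target: cerebellum.CB, kind: excitatory, plastic: true, delay: 4}
  - {source: cortex.Cortex.surprise, target: amygdala.AMY.surprise, kind: excitatory}
  - {source: cerebellum.CB, target: brainstem.EWpg, kind: excitatory}
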