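drosophila_11sp_synthetic.nwk: rooted binary tree of the 11 Drosophila
species on the accepted genus topology, with SYNTHETIC relative-time
branch lengths (root depth 1.0) chosen for testing; not an inferred
chronogram.
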