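# Default scalp regions of interest (10-20-equivalent labels).
# The occipital ROI covers primary/associative visual areas, the prefrontal
# ROI the frontopolar cluster, and the sensorimotor ROI serves as control.
# Replace this file to match a specific montage (e.g. a 128-channel
# HydroCel net); channels absent from the mapping are ignored.
occipital: [O1, Oz, O2, POz, PO3, PO4, PO7, PO8]
prefrontal: [Fp1, Fpz, Fp2, AFz, AF3, AF4]
sensorimotor: [C1, C3, Cz, C2, C4, CP1, CP2]
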