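# Body segment inertial parameters, adult male (adjusted Zatsiorsky fractions).
# mass_fraction: fraction of whole-body mass (per segment; legs counted twice).
# com_fraction: segment CoM position as a fraction of segment length from the
#   proximal end (foot: from the heel along the heel-toe axis).
# gyration_fraction: sagittal radius of gyration about the segment CoM as a
#   fraction of segment length.
# "hat" is the head-arms-trunk remainder lumped with the pelvis; its CoM is
# placed by the pelvis-frame offset in the body model, so com/gyration here
# are nominal bookkeeping values only.
segment	mass_fraction	com_fraction	gyration_fraction	count
foot	0.0137	0.4415	0.2570	2
shank	0.0433	0.4459	0.2550	2
thigh	0.1416	0.4095	0.3290	2
hat	0.6028	0.5000	0.4000	1
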