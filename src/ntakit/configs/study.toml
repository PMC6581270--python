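# Bundled study design: murine pregnancy time course.
# 6 groups, 37 biological samples, 2 injections x 3 technical videos
# per sample = 222 distinct measurements.

seed = 0
n_injections = 2
n_technical = 3
dilutions = [125.0, 250.0, 500.0]
cv_biological = 0.25
cv_injection = 0.05
cv_technical = 0.10
bin_width = 1.0
size_min = 0.0
size_max = 1000.0

[[groups]]
label = "NP"
n_biological = 7
mean_total_concentration = 2.0e10

[[groups]]
label = "GD5.5"
n_biological = 6
mean_total_concentration = 3.0e10

[[groups]]
label = "GD10.5"
n_biological = 6
mean_total_concentration = 4.0e10

[[groups]]
label = "GD14.5"
n_biological = 6
mean_total_concentration = 6.0e10

[[groups]]
label = "GD17.5"
n_biological = 6
mean_total_concentration = 5.5e10

[[groups]]
label = "PP1"
n_biological = 6
mean_total_concentration = 4.0e10
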