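# Orthogonal wavelet analysis low-pass (scaling) filters, one per line:
#   <name> <c0> <c1> ... <c_{L-1}>
# Coefficients are the standard published Daubechies values, listed in
# analysis (decomposition) order: the filter is applied by discrete
# convolution, so c0 multiplies the newest sample.  All other filters
# (analysis high-pass, synthesis pair) are derived from these by the
# orthogonal quadrature-mirror relations.  New orthogonal wavelets can be
# added here without code changes.
haar 7.071067811865475727e-01 7.071067811865475727e-01
db2 -1.294095225512603697e-01 2.241438680420133889e-01 8.365163037378079425e-01 4.829629131445341561e-01
db4 -1.059740178506903170e-02 3.288301166688519656e-02 3.084138183556076399e-02 -1.870348117190930859e-01 -2.798376941685985428e-02 6.308807679298589211e-01 7.148465705529156722e-01 2.303778133088965063e-01
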