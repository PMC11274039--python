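controller,case,activity,rmse_bpm,max_error_pct
classical_fuzzy,case1,rest,2.38,4.88
classical_fuzzy,case1,walking,3.72,7.29
classical_fuzzy,case1,jogging,6.40,8.26
classical_fuzzy,case2,rest,2.07,3.45
classical_fuzzy,case2,walking,4.24,6.34
classical_fuzzy,case2,jogging,3.39,5.31
classical_fuzzy,case3,rest,3.14,5.38
classical_fuzzy,case3,walking,4.73,6.86
classical_fuzzy,case3,jogging,2.76,4.35
classical_fuzzy,case4,rest,3.47,6.45
classical_fuzzy,case4,walking,3.36,4.08
classical_fuzzy,case4,jogging,2.67,4.27
classical_fuzzy,case5,rest,1.81,2.63
classical_fuzzy,case5,walking,2.68,2.84
classical_fuzzy,case5,jogging,2.68,5.01
classical_fuzzy,case6,rest,2.51,4.82
classical_fuzzy,case6,walking,2.27,3.91
classical_fuzzy,case6,jogging,2.45,3.21
fuzzy_pid,case1,rest,1.19,2.63
fuzzy_pid,case1,walking,1.14,2.27
fuzzy_pid,case1,jogging,1.27,1.96
fuzzy_pid,case2,rest,0.91,2.30
fuzzy_pid,case2,walking,0.95,2.15
fuzzy_pid,case2,jogging,1.23,2.77
fuzzy_pid,case3,rest,0.89,2.63
fuzzy_pid,case3,walking,0.87,2.08
fuzzy_pid,case3,jogging,0.62,1.71
fuzzy_pid,case4,rest,1.09,2.13
fuzzy_pid,case4,walking,0.76,1.47
fuzzy_pid,case4,jogging,0.64,1.71
fuzzy_pid,case5,rest,0.89,1.72
fuzzy_pid,case5,walking,1.35,2.27
fuzzy_pid,case5,jogging,1.44,2.51
fuzzy_pid,case6,rest,0.82,1.92
fuzzy_pid,case6,walking,1.15,2.23
fuzzy_pid,case6,jogging,0.66,0.94
rbf_network,case1,rest,0.64,1.68
rbf_network,case1,walking,0.54,0.57
rbf_network,case1,jogging,0.90,1.13
rbf_network,case2,rest,0.45,1.22
rbf_network,case2,walking,0.68,0.64
rbf_network,case2,jogging,0.80,0.54
rbf_network,case3,rest,0.49,1.68
rbf_network,case3,walking,0.53,1.07
rbf_network,case3,jogging,0.71,0.43
rbf_network,case4,rest,0.44,0.78
rbf_network,case4,walking,0.51,0.99
rbf_network,case4,jogging,0.74,0.56
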