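T_K,P_MPa,rho_kg_m3,y,sd_y,sol_g_L
308.2,12,768.52,1.10e-05,4.93e-07,0.0531
308.2,15,816.10,1.45e-05,9.94e-07,0.0760
308.2,18,846.10,1.66e-05,6.99e-07,0.0914
308.2,21,874.55,2.02e-05,6.91e-07,0.1153
308.2,24,895.66,2.67e-05,7.99e-07,0.1565
308.2,27,913.70,2.94e-05,9.69e-07,0.1763
308.2,30,929.85,3.51e-05,1.158e-06,0.2144
318.2,12,659.80,7.4e-06,1.502e-06,0.0292
318.2,15,743.83,1.41e-05,5.90e-07,0.0664
318.2,18,790.29,2.05e-05,8.59e-07,0.1043
318.2,21,823.80,2.61e-05,9.88e-07,0.1397
318.2,24,850.15,3.31e-05,9.99e-07,0.1836
318.2,27,872.14,3.69e-05,1.950e-06,0.2108
318.2,30,890.90,4.02e-05,1.995e-06,0.2351
328.2,12,506.75,6.5e-06,5.74e-07,0.0190
328.2,15,654.94,1.27e-05,8.81e-07,0.0517
328.2,18,724.13,2.26e-05,9.91e-07,0.1044
328.2,21,768.74,3.08e-05,9.81e-07,0.1530
328.2,24,801.92,3.63e-05,1.407e-06,0.1894
328.2,27,828.51,4.18e-05,1.799e-06,0.2262
328.2,30,850.83,4.55e-05,1.347e-06,0.2536
338.2,12,384.17,4.3e-06,3.64e-07,0.0100
338.2,15,555.33,9.9e-06,6.82e-07,0.0337
338.2,18,651.28,2.44e-05,8.98e-07,0.1005
338.2,21,709.59,3.38e-05,1.348e-06,0.1541
338.2,24,751.27,3.94e-05,1.728e-06,0.1918
338.2,27,783.19,4.57e-05,2.982e-06,0.2333
338.2,30,809.68,5.26e-05,1.507e-06,0.2786
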