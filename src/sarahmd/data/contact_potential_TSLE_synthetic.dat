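# Synthetic stand-in contact-potential matrix ('TSLE' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
  0.6944   1.5287   1.4066   1.3318   0.5621   1.3103   1.5541   0.8918   1.4965   0.0487   0.1002   1.5102   0.7172   0.3948   1.2220   0.9356   1.0436   0.9081   1.0083   0.1524
  1.5287   1.5779   1.1925   0.8233   1.6658   1.3425   0.7199   1.3114   1.1436   1.7024   1.3991   1.2659   1.7591   1.5527   1.3214   1.1848   1.2108   1.2717   1.1927   1.7060
  1.4066   1.1925   1.3656   1.1198   1.2818   1.3054   1.3502   1.3375   1.1675   1.4891   1.4764   1.2926   1.4106   1.3255   1.1709   1.4265   1.3919   1.3214   1.1598   1.4652
  1.3318   0.8233   1.1198   1.7769   1.2948   1.4092   1.4421   1.1069   1.2581   1.6939   1.4404   0.9932   1.4398   1.4239   1.0666   1.2445   1.0126   1.5221   1.3764   1.2077
  0.5621   1.6658   1.2818   1.2948   0.4631   1.2220   1.3897   0.9754   1.3718   0.1401   0.0933   1.2742   0.5218   0.3329   1.1568   0.9540   0.9280   0.7695   0.8694   0.1420
  1.3103   1.3425   1.3054   1.4092   1.2220   1.1903   1.2322   1.4476   1.1756   1.5292   1.2686   1.0528   1.3238   1.3769   1.3563   1.3294   1.6393   1.3135   1.2464   1.5563
  1.5541   0.7199   1.3502   1.4421   1.3897   1.2322   1.6498   1.2189   1.2963   1.5241   1.3502   0.8619   1.4842   1.2695   1.1931   1.1259   1.2315   1.2905   1.2268   1.5204
  0.8918   1.3114   1.3375   1.1069   0.9754   1.4476   1.2189   1.2160   1.1943   0.6220   0.8863   1.4107   0.9687   0.9936   1.2624   1.1386   1.1267   0.9561   1.1676   0.8203
  1.4965   1.1436   1.1675   1.2581   1.3718   1.1756   1.2963   1.1943   1.3652   1.4085   1.6567   1.4644   1.1651   1.2360   1.2089   1.4733   1.2241   1.3455   1.3559   1.3055
  0.0487   1.7024   1.4891   1.6939   0.1401   1.5292   1.5241   0.6220   1.4085  -0.5415  -0.4747   1.5440   0.2656  -0.1836   0.8908   0.6474   0.7523   0.8571   0.5551  -0.5793
  0.1002   1.3991   1.4764   1.4404   0.0933   1.2686   1.3502   0.8863   1.6567  -0.4747  -0.2197   1.4499   0.2261   0.0069   1.0762   1.0177   0.9007   0.6932   0.9698  -0.3081
  1.5102   1.2659   1.2926   0.9932   1.2742   1.0528   0.8619   1.4107   1.4644   1.5440   1.4499   1.5963   1.6123   1.3489   1.0853   1.4029   1.3347   1.3981   1.2795   1.6525
  0.7172   1.7591   1.4106   1.4398   0.5218   1.3238   1.4842   0.9687   1.1651   0.2656   0.2261   1.6123   0.5536   0.3868   1.2351   1.0874   0.8310   0.8916   0.9684   0.4647
  0.3948   1.5527   1.3255   1.4239   0.3329   1.3769   1.2695   0.9936   1.2360  -0.1836   0.0069   1.3489   0.3868   0.1714   1.0038   0.8609   0.9447   0.7923   0.9913   0.1192
  1.2220   1.3214   1.1709   1.0666   1.1568   1.3563   1.1931   1.2624   1.2089   0.8908   1.0762   1.0853   1.2351   1.0038   0.9810   1.0173   1.2784   1.0420   1.2860   0.9645
  0.9356   1.1848   1.4265   1.2445   0.9540   1.3294   1.1259   1.1386   1.4733   0.6474   1.0177   1.4029   1.0874   0.8609   1.0173   1.2375   1.3568   1.1751   0.9321   0.9096
  1.0436   1.2108   1.3919   1.0126   0.9280   1.6393   1.2315   1.1267   1.2241   0.7523   0.9007   1.3347   0.8310   0.9447   1.2784   1.3568   1.3190   1.2037   1.2427   0.7724
  0.9081   1.2717   1.3214   1.5221   0.7695   1.3135   1.2905   0.9561   1.3455   0.8571   0.6932   1.3981   0.8916   0.7923   1.0420   1.1751   1.2037   1.1183   1.0821   0.7976
  1.0083   1.1927   1.1598   1.3764   0.8694   1.2464   1.2268   1.1676   1.3559   0.5551   0.9698   1.2795   0.9684   0.9913   1.2860   0.9321   1.2427   1.0821   1.1098   0.7806
  0.1524   1.7060   1.4652   1.2077   0.1420   1.5563   1.5204   0.8203   1.3055  -0.5793  -0.3081   1.6525   0.4647   0.1192   0.9645   0.9096   0.7724   0.7976   0.7806  -0.4021
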