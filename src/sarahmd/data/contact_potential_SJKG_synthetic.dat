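# Synthetic stand-in contact-potential matrix ('SJKG' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
  0.0929   0.8479   0.5289   0.6007  -0.0041   0.6334   0.8228   0.2933   0.5914  -0.3639  -0.1768   0.4969   0.0831  -0.1340   0.4141   0.2834   0.4240   0.3758   0.3658  -0.1650
  0.8479   0.5500   0.1812  -0.1187   0.9018   0.2623  -0.1641   0.6219   0.1973   0.9617   0.8684   0.6609   0.7768   0.7902   0.4981   0.4772   0.4288   0.6385   0.3562   0.9794
  0.5289   0.1812   0.3778   0.2534   0.4020   0.2850   0.2777   0.4541   0.2170   0.8440   0.7403   0.3971   0.5320   0.4808   0.5266   0.4959   0.3880   0.3918   0.5173   0.7987
  0.6007  -0.1187   0.2534   0.9580   0.5779   0.3220   0.7684   0.3315   0.4468   0.8946   0.8408  -0.1041   0.4897   0.5822   0.2755   0.4830   0.3119   0.5716   0.3965   0.7951
 -0.0041   0.9018   0.4020   0.5779  -0.2855   0.5943   0.4991   0.3358   0.5877  -0.3482  -0.3297   0.5671  -0.1904  -0.2551   0.4274   0.2854   0.2818   0.2652   0.2963  -0.5808
  0.6334   0.2623   0.2850   0.3220   0.5943   0.2771   0.2404   0.4412   0.3570   0.8277   0.6433   0.2201   0.5754   0.5460   0.5138   0.4463   0.4449   0.6973   0.4217   0.8368
  0.8228  -0.1641   0.2777   0.7684   0.4991   0.2404   0.8450   0.3462   0.2801   0.7761   0.6746  -0.1801   0.6105   0.7302   0.2340   0.6508   0.4849   0.4760   0.4909   0.9661
  0.2933   0.6219   0.4541   0.3315   0.3358   0.4412   0.3462   0.1486   0.4865   0.0341   0.1859   0.6583   0.1611   0.2482   0.4171   0.2999   0.2778   0.3676   0.4399   0.1084
  0.5914   0.1973   0.2170   0.4468   0.5877   0.3570   0.2801   0.4865   0.2169   0.4983   0.7191   0.2819   0.5215   0.6691   0.3024   0.6637   0.3466   0.2733   0.3936   0.5606
 -0.3639   0.9617   0.8440   0.8946  -0.3482   0.8277   0.7761   0.0341   0.4983  -0.9281  -0.8843   0.7922  -0.1650  -0.3837   0.2916   0.0267   0.1603   0.2152   0.2584  -0.8628
 -0.1768   0.8684   0.7403   0.8408  -0.3297   0.6433   0.6746   0.1859   0.7191  -0.8843  -0.4383   0.9159  -0.0444  -0.4055   0.2298   0.0908   0.2575   0.1008   0.2075  -0.6134
  0.4969   0.6609   0.3971  -0.1041   0.5671   0.2201  -0.1801   0.6583   0.2819   0.7922   0.9159   0.6389   0.6275   0.3796   0.4241   0.3556   0.3688   0.6546   0.3966   0.8296
  0.0831   0.7768   0.5320   0.4897  -0.1904   0.5754   0.6105   0.1611   0.5215  -0.1650  -0.0444   0.6275   0.1728  -0.1110   0.6313   0.2573   0.4085   0.1592   0.2360  -0.4076
 -0.1340   0.7902   0.4808   0.5822  -0.2551   0.5460   0.7302   0.2482   0.6691  -0.3837  -0.4055   0.3796  -0.1110  -0.5046   0.4882   0.2906   0.3285   0.2767   0.2253  -0.4500
  0.4141   0.4981   0.5266   0.2755   0.4274   0.5138   0.2340   0.4171   0.3024   0.2916   0.2298   0.4241   0.6313   0.4882   0.3098   0.3531   0.4508   0.3566   0.4978   0.4817
  0.2834   0.4772   0.4959   0.4830   0.2854   0.4463   0.6508   0.2999   0.6637   0.0267   0.0908   0.3556   0.2573   0.2906   0.3531   0.3036   0.3651   0.3483   0.3528   0.5321
  0.4240   0.4288   0.3880   0.3119   0.2818   0.4449   0.4849   0.2778   0.3466   0.1603   0.2575   0.3688   0.4085   0.3285   0.4508   0.3651   0.4240   0.3666   0.1966   0.1959
  0.3758   0.6385   0.3918   0.5716   0.2652   0.6973   0.4760   0.3676   0.2733   0.2152   0.1008   0.6546   0.1592   0.2767   0.3566   0.3483   0.3666   0.5409   0.2530   0.2124
  0.3658   0.3562   0.5173   0.3965   0.2963   0.4217   0.4909   0.4399   0.3936   0.2584   0.2075   0.3966   0.2360   0.2253   0.4978   0.3528   0.1966   0.2530   0.3502   0.2042
 -0.1650   0.9794   0.7987   0.7951  -0.5808   0.8368   0.9661   0.1084   0.5606  -0.8628  -0.6134   0.8296  -0.4076  -0.4500   0.4817   0.5321   0.1959   0.2124   0.2042  -0.6051
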