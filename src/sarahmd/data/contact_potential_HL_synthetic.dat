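# Synthetic stand-in contact-potential matrix ('HL' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
 -0.3752   0.2750   0.2210   0.2507  -0.3668   0.2204   0.3408  -0.0943   0.2657  -0.6264  -0.5408   0.3855  -0.3701  -0.4645   0.0198  -0.0805  -0.0077   0.0762   0.1022  -0.5895
  0.2750   0.4683   0.2891  -0.0485   0.3290   0.1866  -0.0243   0.3013   0.2804   0.5270   0.3438   0.3768   0.3084   0.4076   0.1898   0.4219   0.2192   0.2380   0.2935   0.4684
  0.2210   0.2891   0.3115   0.3076   0.2412   0.1232   0.1211   0.2275   0.2097   0.2999   0.3303   0.2344   0.3191   0.2695   0.1107   0.1454   0.1519   0.1841   0.2406   0.2301
  0.2507  -0.0485   0.3076   0.4510   0.3258   0.1590   0.3767   0.1775   0.2195   0.3019   0.3197   0.0240   0.1962   0.3723   0.2055   0.1295   0.1780   0.0888   0.2687   0.1819
 -0.3668   0.3290   0.2412   0.3258  -0.4780   0.2102   0.2249  -0.0658   0.2587  -0.6991  -0.6831   0.2158  -0.4541  -0.5945   0.0663  -0.0599  -0.1022  -0.0103   0.0882  -0.7074
  0.2204   0.1866   0.1232   0.1590   0.2102   0.1461   0.2377   0.2031   0.1667   0.2663   0.1990   0.2651   0.2508   0.3234   0.2255   0.1670   0.3005   0.1308   0.1891   0.2460
  0.3408  -0.0243   0.1211   0.3767   0.2249   0.2377   0.3531   0.2018   0.2366   0.3269   0.2387  -0.1253   0.2351   0.2792   0.2406   0.1910   0.1500   0.2272   0.2076   0.3609
 -0.0943   0.3013   0.2275   0.1775  -0.0658   0.2031   0.2018   0.1687   0.1813  -0.2665  -0.2334   0.2065  -0.1141  -0.2431   0.0299  -0.0773   0.1378   0.1226   0.1455  -0.2276
  0.2657   0.2804   0.2097   0.2195   0.2587   0.1667   0.2366   0.1813   0.1167   0.3147   0.1700   0.1207   0.2195   0.2721   0.1706   0.2341   0.3027   0.1791   0.1764   0.2267
 -0.6264   0.5270   0.2999   0.3019  -0.6991   0.2663   0.3269  -0.2665   0.3147  -1.1562  -0.9614   0.3992  -0.6961  -0.6902  -0.0352  -0.1363  -0.1467  -0.0511  -0.1144  -0.9574
 -0.5408   0.3438   0.3303   0.3197  -0.6831   0.1990   0.2387  -0.2334   0.1700  -0.9614  -0.7686   0.3822  -0.5225  -0.6512   0.0164  -0.0767  -0.2250  -0.2068  -0.1305  -0.8551
  0.3855   0.3768   0.2344   0.0240   0.2158   0.2651  -0.1253   0.2065   0.1207   0.3992   0.3822   0.4669   0.2511   0.3390   0.2366   0.2502   0.2727   0.2868   0.2536   0.4092
 -0.3701   0.3084   0.3191   0.1962  -0.4541   0.2508   0.2351  -0.1141   0.2195  -0.6961  -0.5225   0.2511  -0.3863  -0.4370  -0.0234  -0.0556  -0.1449  -0.0088  -0.0154  -0.5314
 -0.4645   0.4076   0.2695   0.3723  -0.5945   0.3234   0.2792  -0.2431   0.2721  -0.6902  -0.6512   0.3390  -0.4370  -0.5620   0.0523  -0.0603  -0.1256  -0.0610   0.0285  -0.7284
  0.0198   0.1898   0.1107   0.2055   0.0663   0.2255   0.2406   0.0299   0.1706  -0.0352   0.0164   0.2366  -0.0234   0.0523   0.1689   0.1826   0.0874   0.1326   0.0732   0.0086
 -0.0805   0.4219   0.1454   0.1295  -0.0599   0.1670   0.1910  -0.0773   0.2341  -0.1363  -0.0767   0.2502  -0.0556  -0.0603   0.1826   0.0162   0.0477   0.1617   0.1057  -0.1913
 -0.0077   0.2192   0.1519   0.1780  -0.1022   0.3005   0.1500   0.1378   0.3027  -0.1467  -0.2250   0.2727  -0.1449  -0.1256   0.0874   0.0477   0.2384   0.1124   0.1557  -0.2087
  0.0762   0.2380   0.1841   0.0888  -0.0103   0.1308   0.2272   0.1226   0.1791  -0.0511  -0.2068   0.2868  -0.0088  -0.0610   0.1326   0.1617   0.1124   0.1130   0.1052  -0.1782
  0.1022   0.2935   0.2406   0.2687   0.0882   0.1891   0.2076   0.1455   0.1764  -0.1144  -0.1305   0.2536  -0.0154   0.0285   0.0732   0.1057   0.1557   0.1052   0.1351  -0.1087
 -0.5895   0.4684   0.2301   0.1819  -0.7074   0.2460   0.3609  -0.2276   0.2267  -0.9574  -0.8551   0.4092  -0.5314  -0.7284   0.0086  -0.1913  -0.2087  -0.1782  -0.1087  -1.0200
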