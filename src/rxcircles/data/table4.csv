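network_id,drug_tweets,drug_tweet_users,mention_tweets,mention_users,topic_correlation,abuse_ge1_users,abuse_ge2_users
1,136,48,55,32,0.28,25,9
2,99,28,22,12,0.26,13,1
3,67,14,26,11,0.06,8,2
4,508,84,290,72,0.59,38,18
5,352,46,97,34,0.69,34,22
6,258,72,37,29,0.92,27,12
7,311,69,40,27,0.76,39,18
8,52,17,14,9,0.1,8,6
9,553,61,142,40,0.83,33,18
10,359,76,156,51,0.89,58,21
11,159,32,73,26,0.72,18,11
12,449,77,300,71,-0.14,36,18
13,446,87,302,84,0.74,73,39
14,378,79,112,42,0.65,55,30
15,629,61,140,42,0.99,34,21
16,75,31,36,23,0.82,28,11
17,512,84,244,64,0.93,58,33
18,91,25,35,20,0.89,9,3
19,75,30,28,17,0.37,17,8
20,75,20,24,16,0.77,10,5
21,143,46,80,36,0.3,25,11
22,512,79,91,48,0.86,54,35
23,417,69,142,47,0.6,52,28
24,387,83,249,70,0.97,60,30
25,247,31,53,21,0.61,19,10
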